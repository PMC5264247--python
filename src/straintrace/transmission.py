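"""Vertical-transmission detection from strain SNV rates.

A species shared between a mother and her infant is called *transmitted*
when their reconstructed strains are too similar to be consistent with the
strain-level variation observed between unrelated subjects in the cohort.
The null model is explicit and conservative: under independent
acquisition, the SNV count over n jointly unmasked columns is
Binomial(n, p0) with p0 the *smallest* background SNV rate observed
between non-pair subjects (the hardest background to beat); the reported
p-value is the lower tail P(K <= observed), Bonferroni-corrected over the
number of pair-species tests.  A transmitted verdict additionally requires
the pair's rate to lie strictly below every background rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AbundanceProfile",
    "TransmissionResult",
    "CohortSummary",
    "estimate_abundance",
    "shared_species",
    "transmission_test",
    "cohort_summary",
]

TRANSMITTED = "transmitted"
NOT_TRANSMITTED = "not-transmitted"
INSUFFICIENT = "insufficient-data"


@dataclass
class AbundanceProfile:
    """Relative abundances (percent) of detected species in one sample."""

    sample: str
    abundances: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be nonnegative")


@dataclass(frozen=True)
class TransmissionResult:
    """Per pair-species strain-identity verdict."""

    pair: str
    species: str
    timepoint: str
    pair_snv_rate: float
    background_rates: tuple[float, ...]
    n_columns: int
    p_value: float | None
    verdict: str


@dataclass
class CohortSummary:
    """Cohort-level roll-up of transmission verdicts."""

    per_pair: dict[str, dict]  # pair -> {shared, transmitted, fraction, species}
    cohort_mean_fraction: float
    replacements: list[tuple[str, str, str]]  # (pair, species, later timepoint)
    indeterminate: list[tuple[str, str, str]]


def estimate_abundance(mean_depths: Mapping[str, float], sample: str) -> AbundanceProfile:
    """Relative abundance from per-species mean marker depth.

    abundance_s = 100 x depth_s / sum_t depth_t.  A simple marker-depth
    estimator standing in for full taxonomic profiling; zero total depth
    yields an empty profile.
    """
    total = sum(mean_depths.values())
    if total <= 0:
        return AbundanceProfile(sample, {})
    return AbundanceProfile(
        sample, {sp: 100.0 * v / total for sp, v in mean_depths.items() if v > 0}
    )


def shared_species(
    mother: AbundanceProfile,
    infant: AbundanceProfile,
    min_abundance: float = 0.1,
    require_both: bool = True,
) -> list[str]:
    """Species shared by a mother-infant pair, sorted by infant abundance
    descending (ties by label).

    By default a species must exceed ``min_abundance`` percent (strictly) in
    *both* members.  ``require_both=False`` relaxes this to detection in both
    members with the abundance threshold met in at least one — the looser
    reading of "detected in at least one infant and the respective mother".
    """
    shared = []
    for sp, a in infant.abundances.items():
        m = mother.abundances.get(sp, 0.0)
        if require_both:
            ok = a > min_abundance and m > min_abundance
        else:
            ok = a > 0 and m > 0 and (a > min_abundance or m > min_abundance)
        if ok:
            shared.append(sp)
    return sorted(shared, key=lambda sp: (-infant.abundances[sp], sp))


def transmission_test(
    pair_rate: float,
    n_columns: int,
    background_rates: Sequence[float],
    alpha: float = 0.05,
    n_tests: int = 1,
) -> tuple[float | None, str]:
    """Strain-identity test for one pair-species.

    Returns (p_value, verdict).  p0 = min(background)/100; observed SNV
    count = round(pair_rate x n_columns / 100); p = P(K <= observed) for
    K ~ Binomial(n_columns, p0).  Verdict is ``transmitted`` iff
    p < alpha / n_tests and pair_rate < min(background).  If the background
    itself contains an identical strain (p0 = 0) the test is not
    applicable and the verdict is ``insufficient-data``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not background_rates:
        return None, INSUFFICIENT
    p0 = min(background_rates) / 100.0
    if p0 <= 0.0:
        return None, INSUFFICIENT
    k = int(round(pair_rate * n_columns / 100.0))
    p_value = float(stats.binom.cdf(k, n_columns, p0))
    if pair_rate >= min(background_rates):
        return p_value, NOT_TRANSMITTED
    verdict = TRANSMITTED if p_value < alpha / n_tests else NOT_TRANSMITTED
    return p_value, verdict


def _timepoint_key(tp: str):
    digits = "".join(ch for ch in tp if ch.isdigit())
    return (int(digits) if digits else 0, tp)


def cohort_summary(
    results: Sequence[TransmissionResult],
    shared: Mapping[str, Sequence[str]],
) -> CohortSummary:
    """Summarize verdicts per pair and cohort-wide.

    ``shared`` maps pair -> shared species list (union over timepoints).
    The per-pair transmitted fraction is transmitted/shared; the cohort
    mean averages pairs with at least one shared species.

    Strain replacement: a pair-species transmitted at an earlier timepoint
    whose later verdict is ``not-transmitted`` with a pair rate at or above
    the minimum background (i.e. the infant now carries a distinct strain).
    If the later timepoint is untestable the event is reported as
    indeterminate, never as replacement.
    """
    per_pair: dict[str, dict] = {}
    transmitted_by_pair: dict[str, set[str]] = {}
    for res in results:
        if res.verdict == TRANSMITTED:
            transmitted_by_pair.setdefault(res.pair, set()).add(res.species)
    fractions = []
    for pair, species_list in shared.items():
        trans = sorted(transmitted_by_pair.get(pair, set()) & set(species_list))
        n_shared = len(set(species_list))
        frac = len(trans) / n_shared if n_shared else 0.0
        per_pair[pair] = {
            "shared": n_shared,
            "transmitted": len(trans),
            "fraction": frac,
            "species": trans,
        }
        if n_shared:
            fractions.append(frac)
    mean_frac = float(np.mean(fractions)) if fractions else 0.0

    replacements: list[tuple[str, str, str]] = []
    indeterminate: list[tuple[str, str, str]] = []
    by_ps: dict[tuple[str, str], list[TransmissionResult]] = {}
    for res in results:
        by_ps.setdefault((res.pair, res.species), []).append(res)
    for (pair, sp), lst in sorted(by_ps.items()):
        lst = sorted(lst, key=lambda r: _timepoint_key(r.timepoint))
        seen_transmitted = False
        for res in lst:
            if res.verdict == TRANSMITTED:
                seen_transmitted = True
            elif seen_transmitted:
                if res.verdict == INSUFFICIENT:
                    indeterminate.append((pair, sp, res.timepoint))
                elif res.background_rates and res.pair_snv_rate >= min(res.background_rates):
                    replacements.append((pair, sp, res.timepoint))
                break
    return CohortSummary(per_pair, mean_frac, replacements, indeterminate)
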