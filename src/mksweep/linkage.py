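"""Informative-cross analysis for achiasmatic Lepidoptera.

Female meiosis has no recombination, so a backcross with a heterozygous
mother (female-informative family) transmits her two haplotypes intact:
a marker allele required for male survival is present in every surviving
son while segregating 1:1 in daughters.  A heterozygous father
(male-informative family) does recombine, which supports both linkage-map
construction and localization of the survival locus by exclusion of
recombinant markers.

Offspring marker scores are binary: 1 means the offspring inherited the
informative parent's suppressor-coupled allele (phase known from the
grandparental cross), 0 the alternative allele, NaN missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "CrossFamily",
    "LinkageMap",
    "CosegregationResult",
    "LocalizationResult",
    "cosegregation_test",
    "localize_region",
    "recombination_fraction",
    "haldane_cm",
    "inverse_haldane",
    "survival_estimate",
]

FEMALE_INFORMATIVE = "female-informative"
MALE_INFORMATIVE = "male-informative"


@dataclass
class CrossFamily:
    """Offspring of one informative backcross.

    ``offspring`` has a ``sex`` column ('M'/'F') plus one column per
    marker with values in {0, 1, NaN}; rows are surviving, genotyped
    offspring.
    """

    family_type: str
    offspring: pd.DataFrame

    def __post_init__(self) -> None:
        if self.family_type not in (FEMALE_INFORMATIVE, MALE_INFORMATIVE):
            raise ValueError(f"unknown family type {self.family_type!r}")
        if "sex" not in self.offspring.columns:
            raise ValueError("offspring table needs a 'sex' column")

    @property
    def markers(self) -> list[str]:
        return [c for c in self.offspring.columns if c != "sex"]

    def sons(self) -> pd.DataFrame:
        return self.offspring[self.offspring["sex"] == "M"]

    def daughters(self) -> pd.DataFrame:
        return self.offspring[self.offspring["sex"] == "F"]


@dataclass
class LinkageMap:
    """Ordered markers with cumulative Haldane positions (cM)."""

    markers: list[str]
    positions_cm: list[float]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.positions_cm):
            raise ValueError("markers and positions differ in length")
        if any(b < a for a, b in zip(self.positions_cm, self.positions_cm[1:])):
            raise ValueError("positions must be non-decreasing")

    @classmethod
    def from_recombination_fractions(
        cls, markers: list[str], adjacent_r: list[float]
    ) -> "LinkageMap":
        pos = [0.0]
        for r in adjacent_r:
            pos.append(pos[-1] + haldane_cm(r))
        return cls(markers, pos)

    def position(self, marker: str) -> float:
        return self.positions_cm[self.markers.index(marker)]


@dataclass
class CosegregationResult:
    marker: str
    n_sons: int
    all_sons_share: bool
    p_sons: float  # P(all n sons share one maternal allele | no association)
    n_daughters: int
    p_daughters_segregation: float | None  # binomial test of ~1:1 in daughters


def cosegregation_test(family: CrossFamily, marker: str) -> CosegregationResult:
    """Test co-segregation of a marker with male survival.

    In a female-informative family, sons all inheriting the same maternal
    allele at a marker has probability 0.5^n under no association.
    Daughters are checked for 1:1 segregation as a sanity report.
    """
    if family.family_type != FEMALE_INFORMATIVE:
        raise ValueError("cosegregation test requires a female-informative family")
    if marker not in family.markers:
        raise KeyError(f"marker {marker!r} not scored in this family")
    sons = family.sons()[marker].dropna()
    if sons.empty:
        raise ValueError(f"no sons scored at marker {marker!r}")
    n = len(sons)
    share = sons.nunique() == 1
    p = 0.5 ** n if share else 1.0
    daughters = family.daughters()[marker].dropna()
    p_d = None
    if len(daughters) > 0:
        p_d = binomtest(int(daughters.sum()), len(daughters), 0.5).pvalue
    return CosegregationResult(
        marker=marker,
        n_sons=n,
        all_sons_share=bool(share),
        p_sons=float(p),
        n_daughters=len(daughters),
        p_daughters_segregation=p_d,
    )


@dataclass
class LocalizationResult:
    retained: list[str]
    recombinant_counts: pd.Series
    #: nearest flanking markers with >= 1 recombinant (None at map ends)
    left_flank: str | None
    right_flank: str | None


def localize_region(family: CrossFamily, lmap: LinkageMap) -> LocalizationResult:
    """Localize the male-survival locus by exclusion of recombinants.

    A marker where one or more surviving sons lack the informative
    parent's suppressor-coupled allele cannot be required for survival.
    Markers retained in all scored sons delimit the candidate region,
    bounded (exclusively) by the nearest flanking markers carrying at
    least one recombinant.
    """
    if family.family_type != MALE_INFORMATIVE:
        raise ValueError("localization requires a male-informative family")
    sons = family.sons()
    order = [m for m in lmap.markers if m in family.markers]
    if not order:
        raise ValueError("no mapped marker scored in this family")
    rec = pd.Series(
        {m: int((sons[m].dropna() == 0).sum()) for m in order}, name="recombinants"
    )
    retained = [m for m in order if rec[m] == 0 and sons[m].notna().any()]
    if not retained:
        return LocalizationResult([], rec, None, None)
    first, last = order.index(retained[0]), order.index(retained[-1])
    left = next((order[i] for i in range(first - 1, -1, -1) if rec[order[i]] > 0), None)
    right = next((order[i] for i in range(last + 1, len(order)) if rec[order[i]] > 0), None)
    return LocalizationResult(retained, rec, left, right)


def recombination_fraction(
    family: CrossFamily, marker_a: str, marker_b: str, conf_level: float = 0.95
) -> dict:
    """Estimate r between two markers from a male-informative family.

    Each offspring is one scored paternal meiosis; r is the fraction of
    offspring whose inheritance differs between the two markers, with a
    Clopper-Pearson binomial CI.  r near 1 indicates a phase error and is
    flagged.
    """
    if family.family_type != MALE_INFORMATIVE:
        raise ValueError("recombination fractions require a male-informative family")
    sub = family.offspring[[marker_a, marker_b]].dropna()
    n = len(sub)
    if n < 2:
        raise ValueError(f"fewer than 2 offspring scored at both {marker_a}/{marker_b}")
    recomb = int((sub[marker_a] != sub[marker_b]).sum())
    r = recomb / n
    ci = binomtest(recomb, n).proportion_ci(confidence_level=conf_level)
    return {
        "r": float(r),
        "n": n,
        "recombinants": recomb,
        "ci": (float(ci.low), float(ci.high)),
        "phase_warning": r > 0.5,
    }


def haldane_cm(r: float) -> float:
    """Haldane map distance d = -50 ln(1 - 2r), in cM."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"r must be in [0, 0.5) for a finite distance, got {r}")
    return float(-50.0 * np.log1p(-2.0 * r))


def inverse_haldane(d_cm: float) -> float:
    """Recombination fraction r = (1 - exp(-d/50)) / 2 for distance in cM."""
    if d_cm < 0:
        raise ValueError("distance must be >= 0")
    return float((1.0 - np.exp(-d_cm / 50.0)) / 2.0)


def survival_estimate(family: CrossFamily, conf_level: float = 0.95) -> dict:
    """Survival of suppressor-carrying males in a male-informative family.

    With a 1:1 primary sex ratio and half of male zygotes inheriting the
    suppressor, the number of daughters halved estimates the number of
    suppressor-bearing male zygotes, so survival = sons / (daughters / 2).
    """
    n_sons = len(family.sons())
    n_daughters = len(family.daughters())
    if n_daughters == 0:
        raise ValueError("survival estimate needs at least one daughter")
    expected_males = n_daughters / 2.0
    surv = n_sons / expected_males
    ci = binomtest(min(n_sons, int(expected_males)), int(round(expected_males))).proportion_ci(
        confidence_level=conf_level
    )
    return {
        "survival": float(surv),
        "n_sons": n_sons,
        "n_daughters": n_daughters,
        "expected_suppressor_males": expected_males,
        "ci": (float(ci.low), float(ci.high)),
    }
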