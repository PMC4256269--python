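"""Deterministic model of a male-killing suppressor sweep with linked neutral loci.

The model tracks, separately for each sex, the frequencies of diplotypes
(unordered pairs of gametic haplotypes) crossed with *Wolbachia* infection
status, in a butterfly population where

* infection is maternally transmitted,
* infected male zygotes die unless rescued by a dominant zygotically acting
  suppressor allele ``S`` (partially so for ``Ss`` heterozygotes),
* infected males induce cytoplasmic incompatibility (CI) against uninfected
  females, and
* recombination occurs in male meiosis only (achiasmatic female meiosis,
  as in the Lepidoptera).

Haplotypes carry the suppressor locus (index 0) plus one or two linked
neutral loci.  Each locus is biallelic: allele ``1`` is the variant carried
by the immigrant suppressor chromosome, allele ``0`` the resident variant.
Generations are discrete and non-overlapping; mating is random; the
population is effectively infinite (no drift).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "PopulationState",
    "Trajectory",
    "ExtinctionError",
    "initial_state",
    "male_gametes",
    "female_gametes",
    "next_generation",
    "run_trajectory",
    "equilibrium_profile",
    "ld_metrics",
    "sample_individuals",
    "LOCUS_ALLELES",
]

#: allele labels per locus index: (resident, immigrant) pairs
LOCUS_ALLELES = (("s", "S"), ("a", "A"), ("b", "B"))

UNINFECTED, INFECTED = 0, 1


class ExtinctionError(RuntimeError):
    """Raised when the surviving mass of one sex reaches zero."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the suppressor-sweep recursion.

    Defaults describe the Samoan situation: 99% of females infected with a
    fully penetrant male-killer, complete CI, suppressed-male survival 0.5
    for ``Ss`` heterozygotes and 1 for ``SS`` homozygotes, and the suppressor
    entering as an infected ``SS`` immigrant male whose matings make up
    ``immigrant_fraction`` of the generation-0 male gamete pool.
    """

    prevalence0: float = 0.99
    survival_ss_male_infected: float = 0.0
    survival_Ss_male_infected: float = 0.5
    survival_SS_male_infected: float = 1.0
    ci_level: float = 1.0
    rec_fractions: tuple[float, ...] = (0.0,)
    immigrant_fraction: float = 0.1

    def __post_init__(self) -> None:
        props = {
            "prevalence0": self.prevalence0,
            "survival_ss_male_infected": self.survival_ss_male_infected,
            "survival_Ss_male_infected": self.survival_Ss_male_infected,
            "survival_SS_male_infected": self.survival_SS_male_infected,
            "ci_level": self.ci_level,
            "immigrant_fraction": self.immigrant_fraction,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_loci not in (2, 3):
            raise ValueError(
                "rec_fractions must have 1 or 2 entries "
                f"(2- or 3-locus model), got {len(self.rec_fractions)}"
            )
        for r in self.rec_fractions:
            if not 0.0 <= r <= 0.5:
                raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")

    @property
    def n_loci(self) -> int:
        return len(self.rec_fractions) + 1

    @property
    def male_survival(self) -> tuple[float, float, float]:
        """Infected-male viability indexed by number of S alleles."""
        return (
            self.survival_ss_male_infected,
            self.survival_Ss_male_infected,
            self.survival_SS_male_infected,
        )


class _StateSpace:
    """Enumeration of haplotypes/diplotypes plus precomputed gamete tables."""

    _cache: dict[tuple, "_StateSpace"] = {}

    def __init__(self, n_loci: int, rec_fractions: tuple[float, ...]):
        self.n_loci = n_loci
        self.rec_fractions = rec_fractions
        self.haplotypes = list(itertools.product((0, 1), repeat=n_loci))
        nH = len(self.haplotypes)
        self.n_hap = nH
        self.diplotypes = [(i, j) for i in range(nH) for j in range(i, nH)]
        self.n_dip = len(self.diplotypes)
        self._dip_index = {d: k for k, d in enumerate(self.diplotypes)}
        # ordered haplotype pair -> unordered diplotype index
        self.pair_index = np.empty((nH, nH), dtype=np.intp)
        for i in range(nH):
            for j in range(nH):
                self.pair_index[i, j] = self._dip_index[(min(i, j), max(i, j))]
        # allele dosage (0, .5 or 1) per diplotype and locus
        self.dosage = np.array(
            [
                [
                    (self.haplotypes[i][l] + self.haplotypes[j][l]) / 2.0
                    for l in range(n_loci)
                ]
                for i, j in self.diplotypes
            ]
        )
        self.n_S = np.array(
            [self.haplotypes[i][0] + self.haplotypes[j][0] for i, j in self.diplotypes]
        )
        self.female_gametes = self._gamete_table(recomb=False)
        self.male_gametes = self._gamete_table(recomb=True)

    @classmethod
    def get(cls, n_loci: int, rec_fractions: tuple[float, ...]) -> "_StateSpace":
        key = (n_loci, tuple(rec_fractions))
        if key not in cls._cache:
            cls._cache[key] = cls(n_loci, rec_fractions)
        return cls._cache[key]

    def dip_index(self, hap_a: tuple[int, ...], hap_b: tuple[int, ...]) -> int:
        i = self.haplotypes.index(tuple(hap_a))
        j = self.haplotypes.index(tuple(hap_b))
        return self.pair_index[i, j]

    def _gamete_table(self, recomb: bool) -> np.ndarray:
        """(n_dip, n_hap) matrix of gamete distributions per diplotype.

        Crossovers in the two adjacent intervals are independent (no
        interference).  Without recombination the two parental haplotypes
        are transmitted at 1/2 each.
        """
        out = np.zeros((self.n_dip, self.n_hap))
        hap_pos = {h: k for k, h in enumerate(self.haplotypes)}
        for k, (i, j) in enumerate(self.diplotypes):
            pair = (self.haplotypes[i], self.haplotypes[j])
            if not recomb:
                out[k, i] += 0.5
                out[k, j] += 0.5
                continue
            for start in (0, 1):
                for flips in itertools.product((0, 1), repeat=self.n_loci - 1):
                    p = 0.5
                    strand = start
                    gamete = [pair[strand][0]]
                    for interval, flip in enumerate(flips):
                        r = self.rec_fractions[interval]
                        p *= r if flip else (1.0 - r)
                        strand ^= flip
                        gamete.append(pair[strand][interval + 1])
                    out[k, hap_pos[tuple(gamete)]] += p
        return out


@dataclass
class PopulationState:
    """Adult diplotype x infection frequencies for one generation.

    ``female`` and ``male`` are ``(n_diplotypes, 2)`` arrays; column 0 is
    uninfected, column 1 infected.  Each sums to 1 over its sex.
    """

    generation: int
    female: np.ndarray
    male: np.ndarray
    params: ModelParams

    @property
    def space(self) -> _StateSpace:
        return _StateSpace.get(self.params.n_loci, self.params.rec_fractions)

    def _sex_array(self, sex: str) -> np.ndarray:
        if sex == "female":
            return self.female
        if sex == "male":
            return self.male
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")

    def allele_frequency(
        self, locus: int, sex: str = "population", infected: bool | None = None
    ) -> float:
        """Frequency of the immigrant-derived allele at ``locus``.

        ``sex='population'`` weights the two sexes equally (each sex
        contributes half of the genes to the next generation).
        """
        if sex == "population":
            return 0.5 * (
                self.allele_frequency(locus, "female", infected)
                + self.allele_frequency(locus, "male", infected)
            )
        arr = self._sex_array(sex)
        w = arr[:, 1] if infected is True else arr[:, 0] if infected is False else arr.sum(axis=1)
        tot = w.sum()
        if tot == 0.0:
            return float("nan")
        return float((w * self.space.dosage[:, locus]).sum() / tot)

    def haplotype_pool(self) -> np.ndarray:
        """Haplotype frequencies carried by adults, sexes weighted equally."""
        sp = self.space
        pool = np.zeros(sp.n_hap)
        for arr in (self.female, self.male):
            mass = arr.sum(axis=1)
            pool += 0.5 * (sp.female_gametes.T @ mass)
        return pool

    def infected_fraction(self, sex: str) -> float:
        return float(self._sex_array(sex)[:, 1].sum())

    def validate(self, atol: float = 1e-12) -> None:
        for name, arr in (("female", self.female), ("male", self.male)):
            if (arr < -atol).any():
                raise ValueError(f"negative frequency in {name} distribution")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies sum to {arr.sum()}, not 1")


def female_gametes(
    diplotype: tuple[tuple[int, ...], tuple[int, ...]],
    params: ModelParams,
) -> dict[tuple[int, ...], float]:
    """Gamete distribution of a female: the two parental haplotypes at 1/2
    each, regardless of recombination fractions (no female recombination)."""
    sp = _StateSpace.get(params.n_loci, params.rec_fractions)
    row = sp.female_gametes[sp.dip_index(*diplotype)]
    return {h: float(p) for h, p in zip(sp.haplotypes, row) if p > 0}


def male_gametes(
    diplotype: tuple[tuple[int, ...], tuple[int, ...]],
    params: ModelParams,
) -> dict[tuple[int, ...], float]:
    """Gamete distribution of a male, with per-interval recombination."""
    sp = _StateSpace.get(params.n_loci, params.rec_fractions)
    row = sp.male_gametes[sp.dip_index(*diplotype)]
    return {h: float(p) for h, p in zip(sp.haplotypes, row) if p > 0}


def initial_state(params: ModelParams) -> PopulationState:
    """Generation-0 adult population.

    Residents are fixed for the resident haplotype (all ``0``); a fraction
    ``prevalence0`` of females is infected.  The male pool contains the
    infected immigrant male, homozygous for the full immigrant haplotype,
    at mass ``immigrant_fraction`` (his share of matings), the remainder
    being uninfected resident males.
    """
    sp = _StateSpace.get(params.n_loci, params.rec_fractions)
    resident = sp.dip_index((0,) * params.n_loci, (0,) * params.n_loci)
    immigrant = sp.dip_index((1,) * params.n_loci, (1,) * params.n_loci)
    female = np.zeros((sp.n_dip, 2))
    male = np.zeros((sp.n_dip, 2))
    female[resident, INFECTED] = params.prevalence0
    female[resident, UNINFECTED] = 1.0 - params.prevalence0
    male[immigrant, INFECTED] = params.immigrant_fraction
    male[resident, UNINFECTED] = 1.0 - params.immigrant_fraction
    return PopulationState(0, female, male, params)


def next_generation(state: PopulationState, params: ModelParams | None = None) -> PopulationState:
    """Advance one generation: random mating, CI mortality, male-killing.

    Zygotes inherit the mother's infection status.  Offspring of
    uninfected mothers sired by infected fathers die at rate ``ci_level``.
    Infected male zygotes survive according to their suppressor genotype;
    females and uninfected males are untouched.  Each sex is renormalized.
    """
    params = params or state.params
    sp = _StateSpace.get(params.n_loci, params.rec_fractions)

    gf = sp.female_gametes.T @ state.female  # (n_hap, 2) by maternal infection
    gm = sp.male_gametes.T @ state.male  # (n_hap, 2) by paternal infection
    gm_tot = gm.sum()
    if gm_tot <= 0.0 or gf.sum() <= 0.0:
        raise ExtinctionError(f"no surviving parents at generation {state.generation}")
    gm = gm / gm_tot  # every adult male gets an equal share of matings

    zygotes = np.zeros((sp.n_dip, 2))  # by maternal (= offspring) infection
    for m_inf in (UNINFECTED, INFECTED):
        for f_inf in (UNINFECTED, INFECTED):
            w = 1.0 - params.ci_level if (m_inf == UNINFECTED and f_inf == INFECTED) else 1.0
            if w == 0.0:
                continue
            outer = np.outer(gf[:, m_inf], gm[:, f_inf]) * w
            np.add.at(zygotes[:, m_inf], sp.pair_index.ravel(), outer.ravel())

    female = zygotes.copy()
    male = zygotes.copy()
    surv = np.asarray(params.male_survival)
    male[:, INFECTED] *= surv[sp.n_S]

    f_tot, m_tot = female.sum(), male.sum()
    if f_tot <= 0.0 or m_tot <= 0.0:
        raise ExtinctionError(f"population extinct at generation {state.generation + 1}")
    return PopulationState(state.generation + 1, female / f_tot, male / m_tot, params)


@dataclass
class Trajectory:
    """Sequence of population states with per-generation summaries."""

    params: ModelParams
    states: list[PopulationState] = field(default_factory=list)

    def summary(self):
        """Per-generation allele frequencies, sex ratio and LD (DataFrame)."""
        import pandas as pd

        rows = []
        for st in self.states:
            row = {"generation": st.generation}
            for l in range(self.params.n_loci):
                lab = LOCUS_ALLELES[l][1]
                row[f"freq_{lab}_pop"] = st.allele_frequency(l, "population")
                row[f"freq_{lab}_female"] = st.allele_frequency(l, "female")
                row[f"freq_{lab}_male"] = st.allele_frequency(l, "male")
            row["infected_female"] = st.infected_fraction("female")
            row["infected_male"] = st.infected_fraction("male")
            for l in range(1, self.params.n_loci):
                ld = ld_metrics(st, (0, l))
                row[f"D_S_{LOCUS_ALLELES[l][1]}"] = ld["D"]
                row[f"r_S_{LOCUS_ALLELES[l][1]}"] = ld["r_corr"]
            rows.append(row)
        return pd.DataFrame(rows)


def run_trajectory(params: ModelParams, T: int) -> Trajectory:
    """Iterate the recursion for ``T`` generations (returns T+1 states)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    traj = Trajectory(params)
    state = initial_state(params)
    traj.states.append(state)
    for _ in range(T):
        state = next_generation(state, params)
        traj.states.append(state)
    return traj


def equilibrium_profile(
    params: ModelParams,
    r_grid,
    tol: float = 1e-10,
    max_gen: int = 5000,
) -> dict[float, dict]:
    """Equilibrium frequency of the hitchhiking allele for each r in ``r_grid``.

    For each recombination fraction the 2-locus model is iterated until the
    largest per-generation change in any state frequency is below ``tol``.
    Non-convergence within ``max_gen`` is flagged, never silently truncated.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    out: dict[float, dict] = {}
    for r in r_grid:
        p = replace(params, rec_fractions=(float(r),))
        state = initial_state(p)
        converged = False
        for _ in range(max_gen):
            nxt = next_generation(state, p)
            delta = max(
                np.abs(nxt.female - state.female).max(),
                np.abs(nxt.male - state.male).max(),
            )
            state = nxt
            if delta < tol:
                converged = True
                break
        out[float(r)] = {
            "frequency": state.allele_frequency(1, "population"),
            "converged": converged,
            "generations": state.generation,
        }
    return out


def ld_metrics(state: PopulationState, locus_pair: tuple[int, int] = (0, 1)) -> dict:
    """Linkage disequilibrium between two loci on the adult haplotype pool.

    Both sexes are pooled with equal weight.  ``D`` is
    ``freq(1,1 haplotype) - p1*p2`` for the immigrant alleles; ``r_corr``
    is the correlation-style normalization.  A monomorphic locus yields
    LD 0 with ``monomorphic=True``.
    """
    la, lb = locus_pair
    sp = state.space
    if max(la, lb) >= sp.n_loci:
        raise ValueError(
            f"locus pair {locus_pair} needs a {max(la, lb) + 1}-locus model, "
            f"state has {sp.n_loci} loci"
        )
    pool = state.haplotype_pool()
    pa = sum(p for h, p in zip(sp.haplotypes, pool) if h[la] == 1)
    pb = sum(p for h, p in zip(sp.haplotypes, pool) if h[lb] == 1)
    pab = sum(p for h, p in zip(sp.haplotypes, pool) if h[la] == 1 and h[lb] == 1)
    denom = pa * (1 - pa) * pb * (1 - pb)
    mono = denom <= 0.0
    D = 0.0 if mono else pab - pa * pb
    return {
        "D": float(D),
        "r_corr": 0.0 if mono else float(D / np.sqrt(denom)),
        "monomorphic": bool(mono),
    }


def sample_individuals(
    state: PopulationState,
    n: int,
    seed: int | np.random.Generator,
    sample_id: str = "sample",
):
    """Draw ``n`` diploids multinomially from the sex-pooled adult pool.

    Returns a phased :class:`~mksweep.popgen.HaplotypeSample`; the locus
    names and allele labels follow :data:`LOCUS_ALLELES` (``S/s`` at the
    suppressor, ``A/a`` and ``B/b`` at the neutral loci).
    """
    from .popgen import HaplotypeSample

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sp = state.space
    dist = 0.5 * (state.female.sum(axis=1) + state.male.sum(axis=1))
    counts = rng.multinomial(n, dist / dist.sum())
    loci = ["suppressor"] + [f"neutral{l}" for l in range(1, sp.n_loci)]
    rows = {}
    ind = 0
    for k, c in enumerate(counts):
        i, j = sp.diplotypes[k]
        for _ in range(c):
            for slot, hap_idx in ((0, i), (1, j)):
                hap = sp.haplotypes[hap_idx]
                rows[(f"ind{ind:04d}", slot)] = [
                    LOCUS_ALLELES[l][hap[l]] for l in range(sp.n_loci)
                ]
            ind += 1
    import pandas as pd

    df = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["individual", "slot"])
    return HaplotypeSample(sample_id=sample_id, haplotypes=df)
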