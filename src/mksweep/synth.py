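"""Synthetic marker panels, time-point samples and mapping crosses.

Generates every input the analysis pipeline consumes, with the statistical
structure the field data are assumed to have: a panel of multi-allelic
intronic markers on the suppressor chromosome (plus unlinked controls) at
linkage equilibrium before the sweep; post-sweep samples whose linked-marker
haplotypes hitchhike with the suppressor according to the deterministic
model at each marker's map-derived recombination fraction; and
female-/male-informative backcross families with achiasmatic female meiosis
and suppressor-dependent male survival.

Every generator takes an explicit seed and returns, alongside the data, a
:class:`SimulationTruth` record sufficient to regenerate it bit-exactly.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import linkage as lk
from . import model as mdl
from .popgen import HaplotypeSample

__all__ = [
    "MarkerPanel",
    "SimulationTruth",
    "make_panel",
    "simulate_sweep_samples",
    "simulate_cross_family",
    "write_fixtures",
]

#: positions (cM) of the 12 linked markers A..L on the suppressor chromosome;
#: anchored to the mapped configuration (C at +8, D/E/F in the +11/+12
#: cluster, G at +17, 41 cM span)
DEFAULT_LINKED_POSITIONS = (0.0, 4.0, 8.0, 11.0, 11.5, 12.0, 17.0, 22.0, 27.0, 32.0, 36.5, 41.0)
DEFAULT_SUPPRESSOR_POS = 11.5
DEFAULT_NOVEL_MARKERS = ("A", "F", "G", "I")

BASES = "ACGT"


@dataclass
class MarkerPanel:
    """Marker definitions: map positions, allele pools, immigrant haplotype."""

    table: pd.DataFrame  # index marker; columns: group, pos_cm, immigrant_allele, novel
    frequencies: dict[str, dict[str, float]]  # marker -> allele -> pre-sweep freq
    sequences: dict[str, dict[str, str]]  # marker -> allele -> aligned sequence
    suppressor_pos_cm: float = DEFAULT_SUPPRESSOR_POS

    @property
    def markers(self) -> list[str]:
        return list(self.table.index)

    @property
    def linked_markers(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "SLG"])

    @property
    def unlinked_markers(self) -> list[str]:
        return list(self.table.index[self.table["group"] != "SLG"])

    def recombination_to_suppressor(self, marker: str) -> float:
        """Map-derived r between a linked marker and the suppressor
        (inverse Haldane of the cM separation)."""
        pos = self.table.loc[marker, "pos_cm"]
        if pd.isna(pos):
            raise ValueError(f"{marker!r} is not on the suppressor linkage group")
        return lk.inverse_haldane(abs(float(pos) - self.suppressor_pos_cm))

    def validate(self) -> None:
        for m, freqs in self.frequencies.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"pre-sweep frequencies at {m} sum to {tot}")
        span = self.table.loc[self.table["group"] == "SLG", "pos_cm"]
        if (span < 0).any():
            raise ValueError("negative map position")


@dataclass
class SimulationTruth:
    """Record of everything needed to regenerate a simulated dataset."""

    seed: int
    model_params: dict
    sample_times: list[int]
    n_individuals: int
    suppressor_pos_cm: float
    r_to_suppressor: dict[str, float]
    immigrant_alleles: dict[str, str]
    novel_markers: list[str]
    expected_immigrant_freq: dict[str, dict[str, float]] = field(default_factory=dict)
    s_frequency: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _broken_stick_frequencies(rng: np.random.Generator, k: int) -> np.ndarray:
    """Pre-sweep allele frequencies: uniform stick-breaking, sorted."""
    f = rng.dirichlet(np.ones(k))
    return np.sort(f)[::-1]


def _allele_sequences(rng: np.random.Generator, alleles: list[str], length: int) -> dict[str, str]:
    """One aligned sequence per allele, differing at binary-coded SNP sites."""
    base = rng.choice(list(BASES), size=length)
    n_sites = max(1, int(np.ceil(np.log2(max(len(alleles), 2)))))
    sites = rng.choice(length, size=n_sites, replace=False)
    derived = {}
    for s in sites:
        alt = [b for b in BASES if b != base[s]]
        derived[s] = rng.choice(alt)
    out = {}
    for i, allele in enumerate(alleles):
        seq = base.copy()
        for bit, s in enumerate(sorted(sites)):
            if (i >> bit) & 1:
                seq[s] = derived[s]
        out[allele] = "".join(seq)
    return out


def make_panel(
    seed: int,
    n_linked: int = 12,
    n_unlinked: int = 9,
    n_novel: int = 4,
    span_cm: float = 41.0,
    allele_range: tuple[int, int] = (2, 8),
    seq_length: int = 500,
    suppressor_pos_cm: float = DEFAULT_SUPPRESSOR_POS,
    positions_cm: tuple[float, ...] | None = None,
    novel_markers: tuple[str, ...] | None = None,
) -> MarkerPanel:
    """Build a marker panel emulating the field marker set.

    Defaults: 12 linked markers (labels A-L) spanning 41 cM with the
    mapped anchor positions, 9 unlinked markers (M-U) on separate linkage
    groups, 2-8 alleles per marker with broken-stick pre-sweep
    frequencies, and novel immigrant alleles at 4 of the linked markers.
    """
    if n_linked < 2:
        raise ValueError("need at least 2 linked markers")
    if not 0 <= n_novel <= n_linked:
        raise ValueError("n_novel must be between 0 and n_linked")
    rng = np.random.default_rng(seed)
    labels = list(string.ascii_uppercase)
    linked = labels[:n_linked]
    unlinked = labels[n_linked : n_linked + n_unlinked]
    if positions_cm is None:
        if n_linked == 12 and span_cm == 41.0:
            positions_cm = DEFAULT_LINKED_POSITIONS
        else:
            positions_cm = tuple(np.linspace(0.0, span_cm, n_linked))
    if len(positions_cm) != n_linked:
        raise ValueError("positions_cm length must equal n_linked")
    if min(positions_cm) < 0 or max(positions_cm) > span_cm:
        raise ValueError("marker positions outside [0, map length]")

    if novel_markers is None:
        if n_novel == 0:
            novel_markers = ()
        elif set(DEFAULT_NOVEL_MARKERS) <= set(linked) and n_novel == 4:
            novel_markers = DEFAULT_NOVEL_MARKERS
        else:
            novel_markers = tuple(
                sorted(rng.choice(linked, size=n_novel, replace=False))
            )
    if not set(novel_markers) <= set(linked):
        raise ValueError("novel markers must be linked markers")

    rows = []
    frequencies: dict[str, dict[str, float]] = {}
    sequences: dict[str, dict[str, str]] = {}
    lo, hi = allele_range
    for idx, m in enumerate(linked + unlinked):
        k = int(rng.integers(lo, hi + 1))
        is_linked = m in linked
        novel = m in novel_markers
        if novel:
            names = [f"{m}{i + 1}" for i in range(k)]
            freqs = _broken_stick_frequencies(rng, k)
            frequencies[m] = dict(zip(names, freqs))
            imm = f"{m}{k + 1}"
            all_names = names + [imm]
        else:
            # the immigrant haplotype carries an existing rare variant:
            # swept alleles are rare or absent before the sweep
            k_res = max(k - 1, 1)
            names = [f"{m}{i + 1}" for i in range(k_res)]
            f_imm = float(rng.uniform(0.02, 0.06))
            freqs = _broken_stick_frequencies(rng, k_res) * (1.0 - f_imm)
            imm = f"{m}{k_res + 1}"
            frequencies[m] = {**dict(zip(names, freqs)), imm: f_imm}
            all_names = names + [imm]
        sequences[m] = _allele_sequences(rng, all_names, seq_length)
        rows.append(
            {
                "marker": m,
                "group": "SLG" if is_linked else f"LG{idx - n_linked + 2}",
                "pos_cm": positions_cm[idx] if is_linked else np.nan,
                "immigrant_allele": imm,
                "novel": novel,
            }
        )
    # 9 unlinked markers on 8 distinct groups: last two share one
    table = pd.DataFrame(rows).set_index("marker")
    if n_unlinked >= 2:
        table.loc[unlinked[-1], "group"] = table.loc[unlinked[-2], "group"]
    panel = MarkerPanel(table, frequencies, sequences, suppressor_pos_cm)
    panel.validate()
    return panel


def _resident_sampler(rng: np.random.Generator, freqs: dict[str, float]):
    names = list(freqs)
    p = np.array([freqs[a] for a in names])
    p = p / p.sum()

    def draw(size: int) -> np.ndarray:
        return rng.choice(names, size=size, p=p)

    return draw


def simulate_sweep_samples(
    panel: MarkerPanel,
    params: mdl.ModelParams | None = None,
    sample_times: tuple[int, ...] = (0, 50),
    n: int = 48,
    seed: int = 0,
    include_suppressor: bool = False,
) -> tuple[list[HaplotypeSample], SimulationTruth]:
    """Draw phased samples of ``n`` diploids at the requested generations.

    Each linked marker hitchhikes according to the deterministic model:
    its marginal immigrant-lineage frequency comes from the two-locus
    recursion at the marker's map-derived recombination fraction to the
    suppressor, and the joint lineage distribution of adjacent map points
    comes from the exact three-locus recursion.  Haplotypes are drawn as a
    Markov walk of the immigrant/resident lineage along the ordered map
    points (markers plus the suppressor), which preserves the exact
    per-marker marginals and reproduces the model's local linkage
    disequilibrium between linked markers.  Generation 0 precedes the
    immigrant: it is drawn at linkage equilibrium from the resident
    pre-sweep frequencies.  Unlinked markers stay at their pre-sweep
    frequencies throughout.
    """
    params = params or mdl.ModelParams()
    if params.n_loci != 2:
        raise ValueError("marker hitchhiking uses the 2-locus model per marker")
    rng = np.random.default_rng(seed)
    horizon = max(sample_times)
    sweep_on = params.immigrant_fraction > 0 and horizon > 0
    times_after_0 = [t for t in sample_times if t > 0]

    r_to_s = {m: panel.recombination_to_suppressor(m) for m in panel.linked_markers}
    # ordered map points; None marks the suppressor itself
    points: list[tuple[float, str | None]] = sorted(
        [(float(panel.table.loc[m, "pos_cm"]), m) for m in panel.linked_markers]
        + [(panel.suppressor_pos_cm, None)],
        key=lambda pm: pm[0],
    )

    def pair_joint(states: dict[int, mdl.PopulationState], near_idx: int, far_idx: int):
        """P(lineage at two loci) per sample time from a model trajectory."""
        out = {}
        for t, st in states.items():
            pool = st.haplotype_pool()
            haps = st.space.haplotypes
            j = np.zeros((2, 2))
            for h, f in zip(haps, pool):
                j[h[near_idx], h[far_idx]] += f
            out[t] = j
        return out

    # marginals per point and joints per adjacent point pair
    marginals: dict[int, dict[int, float]] = {}
    joints: dict[int, dict[int, np.ndarray]] = {}
    s_freq: dict[int, float] = {t: 0.0 for t in sample_times}
    cond: dict[str, dict[int, tuple[float, float]]] = {
        m: {t: (0.0, 0.0) for t in sample_times} for m in panel.linked_markers
    }
    if sweep_on:
        two_locus: dict[str, dict[int, mdl.PopulationState]] = {}
        for m in panel.linked_markers:
            p = dataclasses.replace(params, rec_fractions=(r_to_s[m],))
            traj = mdl.run_trajectory(p, horizon)
            two_locus[m] = {t: traj.states[t] for t in times_after_0}
        any_states = next(iter(two_locus.values()))
        for t, st in any_states.items():
            pool = st.haplotype_pool()
            s_freq[t] = sum(
                f for h, f in zip(st.space.haplotypes, pool) if h[0] == 1
            )
        for m in panel.linked_markers:
            for t, st in two_locus[m].items():
                j = pair_joint({t: st}, 0, 1)[t]
                p_s = j[1].sum()
                cond[m][t] = (
                    j[1, 1] / p_s if p_s > 0 else 0.0,
                    j[0, 1] / (1 - p_s) if p_s < 1 else 0.0,
                )
        for k, (pos, m) in enumerate(points):
            marginals[k] = (
                dict(s_freq)
                if m is None
                else {
                    t: s_freq[t] * cond[m][t][0] + (1 - s_freq[t]) * cond[m][t][1]
                    for t in times_after_0
                }
            )
        for k in range(len(points) - 1):
            (pos_a, ma), (pos_b, mb) = points[k], points[k + 1]
            if ma is None or mb is None:
                marker = mb if ma is None else ma
                # joint with the suppressor from the marker's 2-locus run
                jt = pair_joint(two_locus[marker], 0, 1)
                if ma is None:  # left point is the suppressor
                    joints[k] = jt
                else:
                    joints[k] = {t: j.T for t, j in jt.items()}
            else:
                # both are markers, on the same side of the suppressor:
                # run the 3-locus model ordered S -> nearer -> farther
                d_a = abs(pos_a - panel.suppressor_pos_cm)
                d_b = abs(pos_b - panel.suppressor_pos_cm)
                near, far = (ma, mb) if d_a <= d_b else (mb, ma)
                p3 = dataclasses.replace(
                    params,
                    rec_fractions=(
                        r_to_s[near],
                        lk.inverse_haldane(abs(pos_b - pos_a)),
                    ),
                )
                traj3 = mdl.run_trajectory(p3, horizon)
                jt = pair_joint({t: traj3.states[t] for t in times_after_0}, 1, 2)
                if near is ma:
                    joints[k] = jt
                else:
                    joints[k] = {t: j.T for t, j in jt.items()}

    samplers = {m: _resident_sampler(rng, panel.frequencies[m]) for m in panel.markers}
    samples: list[HaplotypeSample] = []
    for t in sample_times:
        sid = f"gen{t}"
        n_hap = 2 * n
        data: dict[str, np.ndarray] = {}
        lineage_at: dict[str, np.ndarray] = {}
        s_lineage = np.zeros(n_hap, dtype=bool)
        if sweep_on and t > 0:
            # Markov walk of the lineage indicator along the map
            cur = rng.random(n_hap) < marginals[0][t]
            for k, (pos, m) in enumerate(points):
                if k > 0:
                    j = joints[k - 1][t]
                    marg_prev = j.sum(axis=1)
                    p_next = np.where(
                        cur,
                        j[1, 1] / marg_prev[1] if marg_prev[1] > 0 else marginals[k][t],
                        j[0, 1] / marg_prev[0] if marg_prev[0] > 0 else marginals[k][t],
                    )
                    cur = rng.random(n_hap) < p_next
                if m is None:
                    s_lineage = cur.copy()
                else:
                    lineage_at[m] = cur.copy()
        if include_suppressor:
            data["suppressor"] = np.where(s_lineage, "S", "s")
        for m in panel.markers:
            resident = samplers[m](n_hap)
            if sweep_on and t > 0 and m in panel.linked_markers:
                alleles = np.where(
                    lineage_at[m], panel.table.loc[m, "immigrant_allele"], resident
                )
            else:
                alleles = resident
            data[m] = alleles
        index = pd.MultiIndex.from_product(
            [[f"ind{i:04d}" for i in range(n)], [0, 1]], names=["individual", "slot"]
        )
        df = pd.DataFrame(data, index=index)
        samples.append(HaplotypeSample(sample_id=sid, haplotypes=df, sequences=panel.sequences))

    truth = SimulationTruth(
        seed=seed,
        model_params=dataclasses.asdict(params),
        sample_times=list(sample_times),
        n_individuals=n,
        suppressor_pos_cm=panel.suppressor_pos_cm,
        r_to_suppressor=r_to_s,
        immigrant_alleles={
            m: str(panel.table.loc[m, "immigrant_allele"]) for m in panel.linked_markers
        },
        novel_markers=list(panel.table.index[panel.table["novel"]]),
        expected_immigrant_freq={
            f"gen{t}": {
                m: (
                    (lambda c, ps: ps * c[0] + (1 - ps) * c[1])(cond[m][t], s_freq[t])
                    if (sweep_on and t > 0) else 0.0
                )
                for m in panel.linked_markers
            }
            for t in sample_times
        },
        s_frequency={f"gen{t}": (s_freq[t] if sweep_on else 0.0) for t in sample_times},
    )
    return samples, truth


def simulate_cross_family(
    family_type: str,
    n_zygotes: int = 600,
    panel: MarkerPanel | None = None,
    survival: float = 0.4,
    seed: int = 0,
) -> lk.CrossFamily:
    """Simulate an informative backcross with sexed, genotyped survivors.

    The informative parent is heterozygous ``Ss`` with the suppressor-
    coupled allele (scored 1) on the S chromosome at every linked marker;
    the other parent is homozygous.  The mother is *Wolbachia*-infected,
    so male zygotes die unless they inherit S, in which case they survive
    with probability ``survival`` (the empirical suppressed-male
    viability).  Female meiosis transmits whole haplotypes; male meiosis
    recombines with per-interval inverse-Haldane fractions and no
    interference.
    """
    panel = panel or make_panel(seed=0)
    rng = np.random.default_rng(seed)
    markers = panel.linked_markers
    pos = [float(panel.table.loc[m, "pos_cm"]) for m in markers]
    points = sorted(
        [(p, m) for p, m in zip(pos, markers)] + [(panel.suppressor_pos_cm, None)],
        key=lambda pm: pm[0],
    )

    rows = []
    for _ in range(n_zygotes):
        if family_type == lk.FEMALE_INFORMATIVE:
            strand = int(rng.random() < 0.5)
            inherited = {m: strand for _, m in points if m is not None}
            s_allele = strand
        elif family_type == lk.MALE_INFORMATIVE:
            strand = int(rng.random() < 0.5)
            inherited = {}
            s_allele = None
            prev = None
            for p, m in points:
                if prev is not None:
                    r = lk.inverse_haldane(p - prev)
                    if rng.random() < r:
                        strand ^= 1
                if m is None:
                    s_allele = strand
                else:
                    inherited[m] = strand
                prev = p
        else:
            raise ValueError(f"unknown family type {family_type!r}")
        sex = "M" if rng.random() < 0.5 else "F"
        if sex == "M":
            # infected mother: male-killing unless rescued by S
            if s_allele == 0 or rng.random() >= survival:
                continue
        rows.append({"sex": sex, **{m: float(v) for m, v in inherited.items()}})

    df = pd.DataFrame(rows, columns=["sex"] + markers)
    return lk.CrossFamily(family_type=family_type, offspring=df)


def write_fixtures(
    out_dir,
    panel: MarkerPanel,
    samples: list[HaplotypeSample] | None = None,
    truth: SimulationTruth | None = None,
    families: dict[str, lk.CrossFamily] | None = None,
) -> dict[str, str]:
    """Write simulated data in every pipeline input format.

    Emits per-sample phased TSV and IUPAC diploid genotype tables, per-
    marker FASTA allele sequences, per-family segregation tables (JoinMap
    dialect and simple TSV), and the truth record as JSON.  Returns a map
    of artifact name -> path.
    """
    import json
    from pathlib import Path

    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for sample in samples or []:
        p = out / f"{sample.sample_id}_phased.tsv"
        mio.write_phased_tsv(sample, p)
        written[f"phased_{sample.sample_id}"] = str(p)
        p = out / f"{sample.sample_id}_genotypes.tsv"
        mio.write_iupac_table(sample, panel, p)
        written[f"iupac_{sample.sample_id}"] = str(p)
    p = out / "alleles.fasta"
    mio.write_allele_fasta(panel, p)
    written["fasta"] = str(p)
    for name, fam in (families or {}).items():
        p = out / f"{name}_segregation.txt"
        mio.write_joinmap_table(fam, p, name=name)
        written[f"joinmap_{name}"] = str(p)
        p = out / f"{name}_offspring.tsv"
        mio.write_family_tsv(fam, p)
        written[f"family_{name}"] = str(p)
    if truth is not None:
        p = out / "truth.json"
        p.write_text(json.dumps(truth.to_dict(), indent=2))
        written["truth"] = str(p)
    return written
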