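"""Readers and writers for the pipeline's text formats.

Formats: phased-haplotype TSV (individual, locus, allele1, allele2),
diploid SNP genotype tables in single-letter IUPAC codes (heterozygotes as
ambiguity codes, blank = missing), FASTA allele sequences, JoinMap-dialect
segregation tables and a simple offspring TSV for mapping families, and
TSV/JSON writers for sweep reports and LD matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage import FEMALE_INFORMATIVE, MALE_INFORMATIVE, CrossFamily
from .popgen import HaplotypeSample, SweepReport

__all__ = [
    "write_phased_tsv",
    "read_phased_tsv",
    "write_iupac_table",
    "read_iupac_table",
    "phase_unambiguous",
    "write_allele_fasta",
    "read_allele_fasta",
    "write_family_tsv",
    "read_family_tsv",
    "write_joinmap_table",
    "read_joinmap_table",
    "write_sweep_report",
    "ld_strata",
]

MISSING = "NA"

#: unordered base pair -> IUPAC single-letter code
_PAIR_TO_IUPAC = {
    frozenset(v): k for k, v in ambiguous_dna_values.items() if len(v) <= 2 and k != "X"
}


# ---------------------------------------------------------------- phased TSV

def write_phased_tsv(sample: HaplotypeSample, path) -> None:
    """Long-format phased table: individual, locus, allele1, allele2."""
    rows = []
    wide = sample.haplotypes
    for ind in sample.individuals:
        for locus in sample.loci:
            a1 = wide.loc[(ind, 0), locus]
            a2 = wide.loc[(ind, 1), locus]
            rows.append(
                {
                    "individual": ind,
                    "locus": locus,
                    "allele1": MISSING if pd.isna(a1) else a1,
                    "allele2": MISSING if pd.isna(a2) else a2,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phased_tsv(path, sample_id: str | None = None) -> HaplotypeSample:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"individual", "locus", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"phased TSV needs columns {sorted(required)}")
    df = df.replace({MISSING: np.nan, "": np.nan})
    parts = []
    for slot, col in ((0, "allele1"), (1, "allele2")):
        sub = df.pivot(index="individual", columns="locus", values=col)
        sub.index = pd.MultiIndex.from_product(
            [sub.index, [slot]], names=["individual", "slot"]
        )
        parts.append(sub)
    wide = pd.concat(parts).sort_index()
    return HaplotypeSample(
        sample_id=sample_id or Path(path).stem, haplotypes=wide
    )


# ------------------------------------------------------------- IUPAC tables

def _segregating_positions(seq_map: dict[str, str]) -> list[int]:
    seqs = list(seq_map.values())
    return [
        j for j in range(len(seqs[0]))
        if len({s[j] for s in seqs}) > 1
    ]


def write_iupac_table(sample: HaplotypeSample, panel, path) -> None:
    """Diploid SNP genotypes, one row per individual.

    Columns are ``locus:position`` for each segregating site of each
    locus with sequence templates; the cell holds the IUPAC code of the
    individual's two bases at the site (ambiguity code when heterozygous),
    blank when the individual is missing at the locus.
    """
    cols: dict[str, list[str]] = {}
    wide = sample.haplotypes
    for locus in sample.loci:
        seq_map = panel.sequences.get(locus) if panel.sequences else None
        if not seq_map:
            continue
        for pos in _segregating_positions(seq_map):
            vals = []
            for ind in sample.individuals:
                a1 = wide.loc[(ind, 0), locus]
                a2 = wide.loc[(ind, 1), locus]
                if pd.isna(a1) or pd.isna(a2) or a1 not in seq_map or a2 not in seq_map:
                    vals.append("")
                else:
                    pair = frozenset((seq_map[a1][pos], seq_map[a2][pos]))
                    vals.append(_PAIR_TO_IUPAC[pair])
            cols[f"{locus}:{pos}"] = vals
    out = pd.DataFrame(cols, index=pd.Index(sample.individuals, name="individual"))
    out.to_csv(path, sep="\t")


def read_iupac_table(path) -> pd.DataFrame:
    """Read a diploid IUPAC genotype table (blank cells -> NaN)."""
    df = pd.read_csv(path, sep="\t", index_col="individual", dtype=str)
    return df


def phase_unambiguous(genotypes: pd.DataFrame, panel) -> HaplotypeSample:
    """Naive counting-based phasing of IUPAC genotypes.

    For each individual and locus, every unordered pair of panel alleles
    consistent with the observed site codes is enumerated; the allele pair
    is assigned only when exactly one pair is consistent (homozygotes, or
    heterozygotes at a single SNP).  Ambiguous or missing individuals stay
    missing — ambiguity is never resolved silently.
    """
    loci = sorted({c.split(":")[0] for c in genotypes.columns})
    rows = {}
    for ind in genotypes.index:
        assignments: dict[str, tuple[str | float, str | float]] = {}
        for locus in loci:
            seq_map = panel.sequences[locus]
            sites = [
                (int(c.split(":")[1]), c)
                for c in genotypes.columns
                if c.split(":")[0] == locus
            ]
            obs = {pos: genotypes.loc[ind, col] for pos, col in sites}
            if any(pd.isna(v) or v == "" for v in obs.values()):
                assignments[locus] = (np.nan, np.nan)
                continue
            consistent = []
            alleles = list(seq_map)
            for i, a1 in enumerate(alleles):
                for a2 in alleles[i:]:
                    ok = all(
                        frozenset((seq_map[a1][pos], seq_map[a2][pos]))
                        == frozenset(ambiguous_dna_values[code])
                        for pos, code in obs.items()
                    )
                    if ok:
                        consistent.append((a1, a2))
            assignments[locus] = consistent[0] if len(consistent) == 1 else (np.nan, np.nan)
        for slot in (0, 1):
            rows[(ind, slot)] = [assignments[l][slot] for l in loci]
    wide = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    wide.index = pd.MultiIndex.from_tuples(wide.index, names=["individual", "slot"])
    return HaplotypeSample(sample_id="phased", haplotypes=wide.sort_index())


# -------------------------------------------------------------------- FASTA

def write_allele_fasta(panel, path) -> None:
    """All allele sequences, ids ``locus|allele``."""
    records = [
        SeqRecord(Seq(seq), id=f"{locus}|{allele}", description="")
        for locus, seq_map in panel.sequences.items()
        for allele, seq in seq_map.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_allele_fasta(path) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        locus, allele = rec.id.split("|", 1)
        out.setdefault(locus, {})[allele] = str(rec.seq)
    return out


# --------------------------------------------------------- mapping families

def write_family_tsv(family: CrossFamily, path) -> None:
    """Simple offspring table: sex plus markers coded a/b/- .

    ``a`` = the informative parent's suppressor-coupled allele, ``b`` the
    alternative, ``-`` missing.
    """
    df = family.offspring.copy()
    for m in family.markers:
        df[m] = df[m].map({1.0: "a", 0.0: "b"}).fillna("-")
    df.insert(0, "offspring", [f"off{i:04d}" for i in range(len(df))])
    df.insert(0, "family_type", family.family_type)
    df.to_csv(path, sep="\t", index=False)


def read_family_tsv(path) -> CrossFamily:
    df = pd.read_csv(path, sep="\t", dtype=str)
    ftype = df["family_type"].iloc[0] if "family_type" in df else MALE_INFORMATIVE
    markers = [c for c in df.columns if c not in ("family_type", "offspring", "sex")]
    out = pd.DataFrame({"sex": df["sex"]})
    for m in markers:
        out[m] = df[m].map({"a": 1.0, "b": 0.0})
    return CrossFamily(family_type=ftype, offspring=out)


def write_joinmap_table(family: CrossFamily, path, name: str = "family") -> None:
    """JoinMap-dialect segregation file (backcross, phase-known).

    One line per locus: ``locus <ab x aa>`` followed by per-offspring
    genotype codes, ``ab`` when the offspring carries the informative
    parent's suppressor-coupled allele, ``aa`` otherwise, ``--`` missing.
    Offspring sex is recorded in a comment line so the file round-trips.
    """
    lines = [
        f"; segregation data, backcross with heterozygous informative parent",
        f"name = {name}",
        f"popt = BC1",
        f"type = {family.family_type}",
        f"nloc = {len(family.markers)}",
        f"nind = {len(family.offspring)}",
        "; sex  " + " ".join(family.offspring["sex"].tolist()),
    ]
    for m in family.markers:
        codes = [
            "--" if pd.isna(v) else ("ab" if v == 1.0 else "aa")
            for v in family.offspring[m]
        ]
        lines.append(f"{m} <abxaa> " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_joinmap_table(path) -> CrossFamily:
    text = Path(path).read_text().splitlines()
    ftype = MALE_INFORMATIVE
    sexes: list[str] = []
    marker_rows: dict[str, list[float]] = {}
    for line in text:
        line = line.strip()
        if not line:
            continue
        if line.startswith("; sex"):
            sexes = line.split()[2:]
            continue
        if line.startswith(";"):
            continue
        if "=" in line and "<" not in line:
            key, _, val = line.partition("=")
            if key.strip() == "type":
                ftype = val.strip()
            continue
        parts = line.split()
        marker, codes = parts[0], parts[2:]
        marker_rows[marker] = [
            np.nan if c == "--" else (1.0 if c == "ab" else 0.0) for c in codes
        ]
    df = pd.DataFrame(marker_rows)
    df.insert(0, "sex", sexes if sexes else "F")
    return CrossFamily(family_type=ftype, offspring=df)


# ------------------------------------------------------------------ reports

def ld_strata(p: float) -> str:
    """Significance stratum labels used for LD matrices."""
    if pd.isna(p):
        return "NA"
    if p < 0.001:
        return "p<0.001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def write_sweep_report(report: SweepReport, prefix) -> dict[str, str]:
    """Write a sweep report: per-locus TSV, LD matrices, JSON summary."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = {}
    per_locus_path = f"{prefix}_per_locus.tsv"
    report.per_locus.to_csv(per_locus_path, sep="\t")
    written["per_locus"] = per_locus_path
    for sid, mat in report.ld.items():
        p_path = f"{prefix}_ld_{sid}.tsv"
        mat.to_csv(p_path, sep="\t")
        strata = mat.map(ld_strata)
        s_path = f"{prefix}_ld_{sid}_strata.tsv"
        strata.to_csv(s_path, sep="\t")
        written[f"ld_{sid}"] = p_path
    if report.diversity is not None:
        d_path = f"{prefix}_diversity.tsv"
        report.diversity.to_csv(d_path, sep="\t", index=False)
        written["diversity"] = d_path
    summary = {
        "pre": report.pre_id,
        "post": report.post_id,
        "alpha": report.alpha,
        "significant_loci": report.per_locus.index[report.per_locus["holm_reject"]].tolist(),
        "novel_allele_loci": report.per_locus.index[
            report.per_locus["novel_alleles"] != ""
        ].tolist(),
    }
    j_path = f"{prefix}_summary.json"
    Path(j_path).write_text(json.dumps(summary, indent=2))
    written["summary"] = j_path
    return written
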