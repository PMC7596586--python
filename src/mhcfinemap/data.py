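"""Core data containers and on-disk formats.

The pipeline operates on three tables:

* a dosage matrix — samples x variants, each entry the expected count of
  the coded allele per diploid individual, in [0, 2], NaN = missing call;
* a cohort table — per-sample phenotype (0 = control, 1 = case) and
  covariates (age, BMI, cohort label, principal components);
* a protein dictionary — residue carried by each 4-digit HLA allele at
  each polymorphic amino-acid position of a gene.

Dosages travel either as VCF v4.2 with a per-genotype ``DS`` FORMAT field
(HLA alleles and amino-acid markers encoded as biallelic presence/absence
records, SNP2HLA-style) or as an equivalent tab-delimited matrix.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

# Variant categories, from finest sequence resolution to grouped markers.
CAT_SNV = "SNV"
CAT_HLA_2D = "HLA_2d"
CAT_HLA_4D = "HLA_4d"
CAT_AA_RESIDUE = "AA_residue"
CATEGORIES = (CAT_SNV, CAT_HLA_2D, CAT_HLA_4D, CAT_AA_RESIDUE)

#: columns every variant-info table carries (extra columns are preserved).
VARIANT_INFO_COLUMNS = ["chrom", "pos", "category", "gene", "aa_pos", "residue", "est_r2"]

UNKNOWN_RESIDUE = "?"


class ConfigurationError(ValueError):
    """Invalid configuration or thresholds."""


class ParseError(ValueError):
    """Malformed label or file content."""


@dataclass
class DosageMatrix:
    """Samples x variants dosage matrix plus per-variant metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id, one float column per variant id;
        values in [0, 2], NaN marks a missing call.
    variants
        DataFrame indexed by variant id with at least the columns in
        :data:`VARIANT_INFO_COLUMNS`; ``est_r2`` is the imputation-quality
        statistic (NaN for directly genotyped markers).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise ValueError("dosage columns and variant index disagree")
        for col in VARIANT_INFO_COLUMNS:
            if col not in self.variants.columns:
                self.variants[col] = np.nan

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def subset_samples(self, ids) -> "DosageMatrix":
        return DosageMatrix(self.dosages.loc[ids], self.variants.copy())

    def subset_variants(self, ids) -> "DosageMatrix":
        ids = list(ids)
        return DosageMatrix(self.dosages[ids], self.variants.loc[ids].copy())

    def drop_variants(self, ids) -> "DosageMatrix":
        keep = [v for v in self.variant_ids if v not in set(ids)]
        return self.subset_variants(keep)

    def drop_samples(self, ids) -> "DosageMatrix":
        keep = self.sample_ids.difference(pd.Index(ids), sort=False)
        return self.subset_samples(keep)


_ALLELE_RE = re.compile(r"^(?P<gene>[A-Z][A-Z0-9]*)\*(?P<g2>\d+):(?P<g4>\d+)(?::(?P<g6>\d+))*$")


def parse_allele(label: str) -> tuple[str, str, str]:
    """Split a classical HLA allele label into (gene, 2-digit, 4-digit).

    Accepts 4-digit (``B*52:01``) and higher-resolution labels; 6-digit and
    beyond are truncated to 4-digit. Raises :class:`ParseError` otherwise.
    """
    m = _ALLELE_RE.match(label)
    if m is None:
        raise ParseError(f"malformed HLA allele label: {label!r}")
    gene = m.group("gene")
    two = f"{gene}*{m.group('g2')}"
    four = f"{two}:{m.group('g4')}"
    return gene, two, four


@dataclass
class ProteinDictionary:
    """Residues carried by each 4-digit allele of one HLA gene.

    ``table`` is indexed by 4-digit allele label; columns are integer
    amino-acid positions (mature-protein numbering); cells hold one-letter
    residue codes, with ``?`` for unknown.
    """

    gene: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table.columns = [int(c) for c in self.table.columns]

    @property
    def alleles(self) -> list[str]:
        return list(self.table.index)

    @property
    def positions(self) -> list[int]:
        return list(self.table.columns)

    def residue(self, allele: str, position: int) -> str:
        return str(self.table.at[allele, position])

    def residues_at(self, position: int) -> pd.Series:
        """Known residues at a position, allele -> residue (unknowns dropped)."""
        col = self.table[position]
        return col[col != UNKNOWN_RESIDUE]

    def polymorphic_positions(self) -> list[int]:
        """Positions with >= 2 distinct known residues."""
        return [p for p in self.positions if self.residues_at(p).nunique() >= 2]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "allele"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, gene: str | None = None) -> "ProteinDictionary":
        table = pd.read_csv(path, sep="\t", index_col="allele", dtype=str)
        if gene is None:
            gene = "HLA-" + parse_allele(table.index[0])[0]
        return cls(gene=gene, table=table)


# ---------------------------------------------------------------------------
# Cohort / phenotype table
# ---------------------------------------------------------------------------

PHENO_BASE_COLUMNS = ["status", "age", "bmi", "cohort"]


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort table: unique sample ids, binary status, PC columns."""
    if cohort.index.has_duplicates:
        raise ValueError("duplicate sample ids in cohort table")
    missing = [c for c in PHENO_BASE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    status = cohort["status"]
    if not status.isin([0, 1]).all():
        raise ValueError("status must be 0 (control) or 1 (case)")
    return cohort


def pc_columns(cohort: pd.DataFrame) -> list[str]:
    cols = [c for c in cohort.columns if re.fullmatch(r"pc\d+", c)]
    return sorted(cols, key=lambda c: int(c[2:]))


def write_pheno_tsv(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_pheno_tsv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_cohort(cohort)


# ---------------------------------------------------------------------------
# Dosage matrix I/O: tab-delimited and VCF with DS
# ---------------------------------------------------------------------------

def write_dosage_tsv(dm: DosageMatrix, matrix_path, info_path) -> None:
    mat = dm.dosages.copy()
    mat.index.name = "sample_id"
    mat.to_csv(matrix_path, sep="\t")
    info = dm.variants.copy()
    info.index.name = "variant_id"
    info.to_csv(info_path, sep="\t")


def read_dosage_tsv(matrix_path, info_path) -> DosageMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    info = pd.read_csv(info_path, sep="\t", index_col="variant_id")
    return DosageMatrix(mat, info)


def _vcf_header(sample_ids) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##contig=<ID=6,length=171115067>')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                    '"Dosage of the coded (ALT/presence) allele, in [0,2]">')
    header.add_line('##INFO=<ID=CATEGORY,Number=1,Type=String,Description='
                    '"Marker category: SNV, HLA_2d, HLA_4d or AA_residue">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="HLA gene">')
    header.add_line('##INFO=<ID=ER2,Number=1,Type=Float,Description='
                    '"Estimated imputation r2">')
    for sid in sample_ids:
        header.add_sample(str(sid))
    return header


def write_vcf(dm: DosageMatrix, path) -> None:
    """Write dosages as VCF v4.2 with a DS FORMAT field.

    Non-SNV markers become biallelic presence/absence records (REF=A,
    ALT=T is a placeholder pair; DS codes presence of the named marker),
    following the binary-marker convention of SNP2HLA-style panels.
    """
    header = _vcf_header(dm.sample_ids)
    order = np.argsort(dm.variants["pos"].to_numpy(), kind="stable")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for vidx in order:
            vid = dm.variants.index[vidx]
            row = dm.variants.iloc[vidx]
            rec = vf.new_record(
                contig="6",
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row.get("ref", "A") or "A"), str(row.get("alt", "T") or "T")),
                id=str(vid),
            )
            rec.info["CATEGORY"] = str(row["category"])
            if isinstance(row.get("gene"), str) and row["gene"]:
                rec.info["GENE"] = row["gene"]
            if np.isfinite(row.get("est_r2", np.nan)):
                rec.info["ER2"] = float(row["est_r2"])
            ds = dm.dosages[vid].to_numpy()
            for sample, d in zip(rec.samples.values(), ds):
                sample["DS"] = None if np.isnan(d) else float(d)
            vf.write(rec)


def read_vcf(path) -> DosageMatrix:
    """Read a DS-dosage VCF written by :func:`write_vcf` (or compatible)."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        cols: dict[str, np.ndarray] = {}
        rows = []
        for rec in vf:
            ds = np.array(
                [np.nan if s.get("DS") is None else float(s["DS"]) for s in rec.samples.values()],
                dtype=float,
            )
            vid = rec.id
            cols[vid] = ds
            rows.append({
                "variant_id": vid,
                "chrom": rec.contig,
                "pos": rec.pos,
                "category": rec.info.get("CATEGORY", CAT_SNV),
                "gene": rec.info.get("GENE", ""),
                "aa_pos": np.nan,
                "residue": "",
                "est_r2": float(rec.info["ER2"]) if "ER2" in rec.info else np.nan,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "T",
            })
    info = pd.DataFrame(rows).set_index("variant_id")
    mat = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    return DosageMatrix(mat, info)


def write_truth_json(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")
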