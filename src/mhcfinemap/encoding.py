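"""Multi-resolution encoding of imputed HLA variation.

Expands 4-digit classical-allele dosages into the four marker resolutions
the association stage tests — biallelic SNVs, 2-digit and 4-digit HLA
alleles, amino-acid residue markers, and multiallelic amino-acid position
groups — and applies the post-imputation filters (MAF >= 0.01 in both
cases and controls; estimated imputation r2 >= 0.5) and the MHC window
(chromosome 6, 24-36 Mb, GRCh37, inclusive).

Dosage is conserved by construction: a 2-digit allele's dosage is the sum
over its 4-digit members, and a residue's dosage the sum over alleles
carrying it, so per individual and fully-known position the residue
dosages sum to the gene's total allele dosage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import (
    CAT_AA_RESIDUE,
    CAT_HLA_2D,
    CAT_HLA_4D,
    CAT_SNV,
    ConfigurationError,
    DosageMatrix,
    ProteinDictionary,
    UNKNOWN_RESIDUE,
    parse_allele,
)

__all__ = [
    "MarkerTable",
    "two_digit_from_four",
    "residue_dosages",
    "build_marker_table",
    "compute_group_mafs",
    "post_imputation_filter",
    "region_filter",
    "MHC_WINDOW",
]

#: MHC region window (GRCh37, chromosome 6, inclusive 1-based bounds).
MHC_WINDOW = (24_000_000, 36_000_000)


class MarkerTable(DosageMatrix):
    """Analysis-ready marker set: dosages, metadata and position groups.

    ``groups`` maps an amino-acid position group id (e.g. ``HLA-B_171``)
    to its member residue-marker ids; each group has m >= 2 members and
    every residue marker belongs to exactly one group.
    """

    def __init__(self, dosages: pd.DataFrame, variants: pd.DataFrame,
                 groups: dict[str, list[str]] | None = None,
                 log: list[str] | None = None) -> None:
        super().__init__(dosages, variants)
        self.groups = groups or {}
        self.log = log or []

    def _restrict(self, keep_ids) -> "MarkerTable":
        keep = [v for v in self.variant_ids if v in set(keep_ids)]
        groups = {}
        for gid, members in self.groups.items():
            kept = [m for m in members if m in set(keep)]
            if len(kept) >= 2:
                groups[gid] = kept
        return MarkerTable(self.dosages[keep], self.variants.loc[keep].copy(),
                           groups, list(self.log))


def two_digit_from_four(four_digit: pd.DataFrame,
                        log: list[str] | None = None) -> pd.DataFrame:
    """Collapse 4-digit allele dosages to 2-digit alleles by summation.

    6-digit and finer labels are accepted by truncation (logged). Dosages
    are clamped into [0, 2] only against floating error; a clamp larger
    than 1e-6 is logged.
    """
    groups: dict[str, list[str]] = {}
    for label in four_digit.columns:
        gene, two, four = parse_allele(label)
        if four != label and log is not None:
            log.append(f"two_digit_from_four: truncated {label} to {four}")
        groups.setdefault(two, []).append(label)
    out = {}
    for two, members in groups.items():
        s = four_digit[members].sum(axis=1)
        over = float(np.maximum(s - 2.0, 0.0).max()) + float(np.maximum(-s, 0.0).max())
        if over > 1e-6 and log is not None:
            log.append(f"two_digit_from_four: clamped {two} by up to {over:.3g}")
        out[two] = s.clip(0.0, 2.0)
    return pd.DataFrame(out, index=four_digit.index)


def residue_dosages(four_digit: pd.DataFrame, dictionary: ProteinDictionary,
                    log: list[str] | None = None
                    ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Amino-acid residue dosages and position groups from allele dosages.

    The dosage of residue R at position q is the summed dosage of the
    4-digit alleles carrying R at q. Alleles with unknown residue are
    excluded from that position (logged), shrinking its denominator.
    Positions with a single known residue are dropped (monomorphic,
    logged); each retained position contributes one group of its m >= 2
    residue markers.
    """
    unknown = set(four_digit.columns) - set(dictionary.alleles)
    if unknown:
        raise ConfigurationError(
            f"alleles missing from the protein dictionary: {sorted(unknown)}")
    cols: dict[str, pd.Series] = {}
    groups: dict[str, list[str]] = {}
    for pos in dictionary.positions:
        res_of = {a: dictionary.residue(a, pos) for a in four_digit.columns}
        skipped = [a for a, r in res_of.items() if r == UNKNOWN_RESIDUE]
        if skipped and log is not None:
            log.append(f"residue_dosages: position {pos} drops unknown-residue "
                       f"alleles {skipped}")
        known = {a: r for a, r in res_of.items() if r != UNKNOWN_RESIDUE}
        residues = sorted(set(known.values()))
        if len(residues) < 2:
            if log is not None:
                log.append(f"residue_dosages: position {pos} monomorphic, dropped")
            continue
        gid = f"{dictionary.gene}_{pos}"
        members = []
        for r in residues:
            mid = f"{dictionary.gene}_{pos}_{r}"
            alleles = [a for a, rr in known.items() if rr == r]
            s = four_digit[alleles].sum(axis=1)
            over = float(np.maximum(s - 2.0, 0.0).max()) + float(np.maximum(-s, 0.0).max())
            if over > 1e-6 and log is not None:
                log.append(f"residue_dosages: clamped {mid} by up to {over:.3g} "
                           f"(noisy allele dosages)")
            cols[mid] = s.clip(0.0, 2.0)
            members.append(mid)
        groups[gid] = members
    return pd.DataFrame(cols, index=four_digit.index), groups


def compute_group_mafs(dosages: pd.DataFrame, status: pd.Series) -> pd.DataFrame:
    """Per-marker MAF within cases and controls: min(p, 1-p), p = mean/2."""
    st = status.loc[dosages.index]
    out = {}
    for name, grp in (("maf_case", 1), ("maf_control", 0)):
        sub = dosages[st == grp]
        if len(sub) == 0:
            raise ConfigurationError(f"empty {'case' if grp else 'control'} group")
        p = sub.mean(axis=0) / 2.0
        out[name] = np.minimum(p, 1.0 - p)
    return pd.DataFrame(out)


def build_marker_table(dosages: DosageMatrix, dictionary: ProteinDictionary,
                       status: pd.Series, gene_pos: int | None = None) -> MarkerTable:
    """Assemble the full four-resolution marker table from a dosage matrix.

    SNV and 4-digit allele columns are carried through; 2-digit alleles
    and residue markers are derived by summation, inherit the gene's
    coordinate, and carry no estimated r2 of their own (treated as
    passing the imputation-quality filter).
    """
    log: list[str] = []
    info = dosages.variants
    four_ids = [v for v in dosages.variant_ids if info.at[v, "category"] == CAT_HLA_4D]
    snv_ids = [v for v in dosages.variant_ids if info.at[v, "category"] == CAT_SNV]
    four = dosages.dosages[four_ids]
    gene = dictionary.gene
    if gene_pos is None:
        gene_pos = int(info.loc[four_ids, "pos"].iloc[0]) if four_ids else 0

    two = two_digit_from_four(four, log)
    residues, groups = residue_dosages(four, dictionary, log)

    frames = [dosages.dosages[snv_ids], four, two, residues]
    mat = pd.concat(frames, axis=1)

    rows = [info.loc[snv_ids], info.loc[four_ids]]
    extra = []
    for vid in two.columns:
        extra.append({"variant_id": vid, "chrom": "6", "pos": gene_pos,
                      "category": CAT_HLA_2D, "gene": gene, "aa_pos": np.nan,
                      "residue": "", "est_r2": np.nan})
    for gid, members in groups.items():
        pos_label = int(gid.rsplit("_", 1)[1])
        for mid in members:
            extra.append({"variant_id": mid, "chrom": "6", "pos": gene_pos,
                          "category": CAT_AA_RESIDUE, "gene": gene,
                          "aa_pos": pos_label, "residue": mid.rsplit("_", 1)[1],
                          "est_r2": np.nan})
    rows.append(pd.DataFrame(extra).set_index("variant_id"))
    meta = pd.concat(rows)[["chrom", "pos", "category", "gene", "aa_pos", "residue", "est_r2"]]
    mafs = compute_group_mafs(mat, status)
    meta = meta.join(mafs)
    return MarkerTable(mat[list(meta.index)], meta, groups, log)


def post_imputation_filter(markers: MarkerTable, status: pd.Series,
                           maf_min: float = 0.01, r2_min: float = 0.5) -> MarkerTable:
    """Keep markers with MAF >= floor in both cases and controls and
    (missing or >=) estimated imputation r2; both bounds inclusive."""
    mafs = compute_group_mafs(markers.dosages, status)
    r2 = markers.variants["est_r2"]
    keep = mafs.index[
        (mafs["maf_case"] >= maf_min)
        & (mafs["maf_control"] >= maf_min)
        & (r2.isna() | (r2 >= r2_min))
    ]
    out = markers._restrict(keep)
    out.log.append(
        f"post_imputation_filter: retained {len(out.variant_ids)} of "
        f"{len(markers.variant_ids)} markers (MAF>={maf_min} both groups, r2>={r2_min})"
    )
    return out


def region_filter(markers: MarkerTable, window=MHC_WINDOW, chrom: str = "6") -> MarkerTable:
    """Keep markers inside the MHC window (1-based inclusive bounds).

    Markers with a missing coordinate are excluded with a log entry.
    """
    lo, hi = window
    pos = pd.to_numeric(markers.variants["pos"], errors="coerce")
    on_chrom = markers.variants["chrom"].astype(str) == str(chrom)
    missing = pos.isna()
    keep = markers.variants.index[on_chrom & ~missing & (pos >= lo) & (pos <= hi)]
    out = markers._restrict(keep)
    n_missing = int(missing.sum())
    if n_missing:
        out.log.append(f"region_filter: {n_missing} markers lacked coordinates (excluded)")
    out.log.append(f"region_filter: retained {len(out.variant_ids)} markers in "
                   f"{chrom}:{lo}-{hi}")
    return out
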