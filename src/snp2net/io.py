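"""Readers and writers for the pipeline's external formats.

Modules travel as GMT (one module per line: name, description, then
tab-separated gene symbols); everything else is headered TSV, with the
common whitespace-delimited PLINK ``.ld`` dialect (columns SNP_A, SNP_B, R2)
accepted for LD tables.  Gene identifiers are opaque case-sensitive strings;
coordinates are 1-based.  p-value columns are validated into (0, 1] with a
hard failure on violations.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .module_scoring import CoexpressionModule

logger = logging.getLogger(__name__)

__all__ = [
    "read_modules",
    "write_modules",
    "read_disease_snps",
    "read_eqtl_table",
    "read_esnp_map",
    "read_ld_table",
    "read_gwas",
    "gwas_to_dict",
    "read_matrix",
    "write_matrix",
    "write_tsv",
    "load_packaged_disease_snps",
]


def read_modules(paths) -> list[CoexpressionModule]:
    """Parse GMT files into coexpression modules.

    ``paths`` is one path or an iterable of paths.  Each line must carry at
    least three tab-separated fields (name, description, >=1 gene).  The
    source label is the description field, falling back to the file stem.
    Duplicate genes within a line are deduplicated with a warning.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    modules = []
    for path in paths:
        path = Path(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: malformed GMT line "
                        f"(expected >=3 tab-separated fields, got {len(fields)})"
                    )
                name, desc = fields[0], fields[1]
                genes = [g for g in fields[2:] if g]
                if len(set(genes)) < len(genes):
                    logger.warning(
                        "%s:%d: module %s has duplicate gene entries; deduplicated",
                        path, lineno, name,
                    )
                modules.append(
                    CoexpressionModule(
                        module_id=name,
                        source=desc or path.stem,
                        genes=frozenset(genes),
                    )
                )
    return modules


def write_modules(modules: Iterable[CoexpressionModule], path) -> None:
    """Write modules as GMT, genes in sorted order for reproducibility."""
    with open(path, "w") as fh:
        for m in modules:
            fh.write("\t".join([m.module_id, m.source, *sorted(m.genes)]) + "\n")


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str):
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def _validate_p(frame: pd.DataFrame, column: str, what: str) -> pd.DataFrame:
    p = pd.to_numeric(frame[column], errors="coerce")
    bad = frame.index[p.isna() | (p <= 0) | (p > 1)]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"{what}: column {column!r} must lie in (0, 1]; "
            f"first violation at row {row}: {frame.loc[row, column]!r}"
        )
    frame = frame.copy()
    frame[column] = p
    return frame


def read_disease_snps(path) -> pd.DataFrame:
    """Disease SNP table: rsid, chromosome, position, functional_type, adjacent_gene."""
    t = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chromosome": str})
    _require_columns(t, ["rsid"], "disease SNP table")
    if t["rsid"].duplicated().any():
        dup = t.loc[t["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"disease SNP table: duplicate rsid {dup!r}")
    for col, default in (("chromosome", ""), ("position", np.nan),
                         ("functional_type", ""), ("adjacent_gene", "")):
        if col not in t.columns:
            t[col] = default
    t["adjacent_gene"] = t["adjacent_gene"].fillna("")
    t["position"] = pd.to_numeric(t["position"], errors="coerce")
    return t


def read_eqtl_table(path) -> pd.DataFrame:
    """cis-eQTL associations: rsid, gene, p_value (+ tissue, snp_pos/gene_pos)."""
    t = pd.read_csv(path, sep="\t")
    _require_columns(t, ["rsid", "gene", "p_value"], "eQTL table")
    return _validate_p(t, "p_value", "eQTL table")


def read_esnp_map(path) -> pd.DataFrame:
    """Genome-wide-significant eSNP map: gene, rsid."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(t, ["gene", "rsid"], "eSNP map")
    return t


def read_ld_table(path) -> pd.DataFrame:
    """LD pairs as headered TSV (rsid_a, rsid_b, r2) or PLINK .ld dialect.

    The ``.ld`` dialect is whitespace-delimited with columns SNP_A, SNP_B
    and R2 (extra columns such as CHR_A/BP_A are ignored).
    """
    with open(path) as fh:
        header = fh.readline()
    if "SNP_A" in header.split():
        t = pd.read_csv(path, sep=r"\s+")
        t = t.rename(columns={"SNP_A": "rsid_a", "SNP_B": "rsid_b", "R2": "r2"})
    else:
        t = pd.read_csv(path, sep="\t")
    _require_columns(t, ["rsid_a", "rsid_b", "r2"], "LD table")
    t["r2"] = pd.to_numeric(t["r2"], errors="coerce")
    bad = t.index[t["r2"].isna() | (t["r2"] < 0) | (t["r2"] > 1)]
    if len(bad):
        raise ValueError(f"LD table: R^2 outside [0, 1] at row {int(bad[0])}")
    return t[["rsid_a", "rsid_b", "r2"]]


def read_gwas(path) -> pd.DataFrame:
    """GWAS summary statistics: rsid, p — unique rsids, p in (0, 1]."""
    t = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    _require_columns(t, ["rsid", "p"], "GWAS table")
    if t["rsid"].duplicated().any():
        dup = t.loc[t["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"GWAS table: duplicate rsid {dup!r}")
    return _validate_p(t, "p", "GWAS table")


def gwas_to_dict(gwas: pd.DataFrame) -> dict:
    return dict(zip(gwas["rsid"], gwas["p"]))


def read_matrix(path) -> pd.DataFrame:
    """Individuals x features TSV matrix; first column holds individual IDs."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="id")


def write_tsv(frame: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Deterministic TSV output (fixed float formatting, no index)."""
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def load_packaged_disease_snps() -> pd.DataFrame:
    """The packaged table of 32 replicated type 2 diabetes SNPs.

    The published table prints no base-pair positions, so the position
    column is empty; SNPs without positions are skipped (with a warning) by
    the matrix-based cis mapping path and this table is chiefly useful with
    a precomputed eQTL association table.
    """
    with resources.as_file(
        resources.files("snp2net.data").joinpath("t2d_snps.tsv")
    ) as p:
        return read_disease_snps(p)
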