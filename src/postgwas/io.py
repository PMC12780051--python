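"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* Summary statistics use the GCTA ``.ma`` dialect: whitespace-delimited
  columns ``SNP CHR BP A1 A2 FREQ BETA SE P`` with a header line. ``BP`` is
  1-based. ``A1`` is the effect allele.
* Peaks and elements are BED: 0-based half-open intervals, no header.
* Contact maps are triplet text (``bin_i bin_j count``) preceded by
  ``#key=value`` header lines carrying at least the bin ``resolution``.
* Position frequency matrices are parsed with :mod:`Bio.motifs`
  (JASPAR ``.jaspar``/``.pfm`` dialects).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

MA_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P"]

INSTRUMENT_COLUMNS = ["SNP", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "A1", "A2"]


def read_ma(path) -> pd.DataFrame:
    """Read a ``.ma``-dialect summary-statistics table."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns {missing}")
    df["CHR"] = df["CHR"].astype(str)
    return df


def write_ma(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=[c for c in MA_COLUMNS if c in df.columns])


def read_bed(path, extra_names=()) -> pd.DataFrame:
    """Read BED3+ intervals; extra columns are named from ``extra_names``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end"] + list(extra_names)
    df.columns = names[: df.shape[1]] + [f"col{i}" for i in range(len(names), df.shape[1])]
    df["chrom"] = df["chrom"].astype(str)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path, extra_cols=()) -> None:
    cols = ["chrom", "start", "end"] + list(extra_cols)
    df.to_csv(path, sep="\t", index=False, header=False, columns=cols)


def read_contacts(path):
    """Read a triplet contact-map file.

    Returns ``(matrix, resolution)`` where the matrix is dense and symmetric.
    """
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            else:
                i, j, c = line.split()
                rows.append((int(i), int(j), float(c)))
    if "resolution" not in meta:
        raise ValueError(f"contact file {path} lacks a '#resolution=' header")
    resolution = int(meta["resolution"])
    n = int(meta.get("n_bins", max(max(i, j) for i, j, _ in rows) + 1 if rows else 0))
    mat = np.zeros((n, n))
    for i, j, c in rows:
        mat[i, j] = c
        mat[j, i] = c
    return mat, resolution


def write_contacts(matrix: np.ndarray, resolution: int, path) -> None:
    n = matrix.shape[0]
    with open(path, "w") as fh:
        fh.write(f"#resolution={resolution}\n#n_bins={n}\n")
        ii, jj = np.nonzero(np.triu(matrix))
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{matrix[i, j]:g}\n")


def read_tss_table(path) -> pd.DataFrame:
    """Read a gene/TSS table: columns ``gene chrom tss strand`` (+optional
    ``start end`` gene-body bounds)."""
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("gene", "chrom", "tss"):
        if col not in df.columns:
            raise ValueError(f"TSS table {path} lacks column {col!r}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_instruments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in INSTRUMENT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"instrument table {path} lacks columns {missing}")
    return df


def write_instruments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pfms(path) -> list:
    """Read position frequency matrices from a JASPAR-format file.

    Returns a list of ``(motif_id, counts)`` with counts as a (4, k) array in
    A, C, G, T order.
    """
    from Bio import motifs as bio_motifs

    path = Path(path)
    fmt = "jaspar" if path.suffix in {".jaspar", ".txt"} else "pfm"
    out = []
    with open(path) as fh:
        if fmt == "jaspar":
            records = bio_motifs.parse(fh, "jaspar")
        else:
            records = [bio_motifs.read(fh, "pfm")]
        for m in records:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append((getattr(m, "matrix_id", None) or m.name or "motif", counts))
    return out


def read_dosage_panel(prefix):
    """Read an LD panel written by :func:`write_dosage_panel`.

    ``prefix.variants.tsv`` holds the variant table, ``prefix.dosage.tsv`` the
    individuals × variants dosage matrix.
    """
    from .sumstats import LDPanel

    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    variants["CHR"] = variants["CHR"].astype(str)
    dosages = np.loadtxt(f"{prefix}.dosage.tsv")
    if dosages.ndim == 1:
        dosages = dosages[:, None]
    return LDPanel(dosages=dosages, variants=variants)


def write_dosage_panel(panel, prefix) -> None:
    panel.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.dosage.tsv", panel.dosages, fmt="%d")
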