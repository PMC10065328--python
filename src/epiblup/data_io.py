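"""Input/output for genotype panels, phenotype tables and relationship kernels.

All predictors handled by this package are binary: doubled-haploid (DH)
lines are fully homozygous, so a SNP is coded 0/1 (one of two homozygous
states), and a haplotype-block variant is a 0/1 carrier indicator.  Loaders
enforce that coding and reject (or, in lenient mode, impute) anything else.

Also provides a sliding-window variance-inflation-factor (VIF) pruning
utility in the spirit of PLINK's ``--indep 50 5 2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("epiblup")

__all__ = [
    "PredictorPanel",
    "PhenotypeRecords",
    "read_predictor_panel",
    "read_phenotypes",
    "vif_prune",
    "write_kernel",
    "read_kernel",
    "write_panel",
]


@dataclass
class PredictorPanel:
    """Lines x binary predictors (SNPs or haplotype-block variants).

    Parameters
    ----------
    line_ids : ordered unique line identifiers (length n).
    predictor_ids : ordered unique predictor identifiers (length p).
    kind : ``"snp"`` or ``"block"``.
    matrix : (n, p) array with entries in {0, 1}; uint8.
    chrom, pos : optional per-predictor map coordinates (1-based positions).
    """

    line_ids: list[str]
    predictor_ids: list[str]
    kind: Literal["snp", "block"]
    matrix: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n, p = self.matrix.shape
        if n < 2 or p < 1:
            raise ValueError(f"panel must have n >= 2 lines and p >= 1 predictors, got {n} x {p}")
        if len(self.line_ids) != n or len(self.predictor_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line_ids")
        if len(set(self.predictor_ids)) != p:
            raise ValueError("duplicate predictor_ids")
        if self.kind not in ("snp", "block"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")
        vals = np.unique(self.matrix)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"panel entries must be in {{0,1}}; found {vals[:5]}")
        self.matrix = self.matrix.astype(np.uint8)

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.matrix.shape[1]

    def subset_predictors(self, idx: Sequence[int]) -> "PredictorPanel":
        idx = np.asarray(idx, dtype=int)
        return PredictorPanel(
            line_ids=list(self.line_ids),
            predictor_ids=[self.predictor_ids[i] for i in idx],
            kind=self.kind,
            matrix=self.matrix[:, idx],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[idx],
            pos=None if self.pos is None else np.asarray(self.pos)[idx],
        )


@dataclass
class PhenotypeRecords:
    """Long-format phenotype BLUEs keyed by (line_id, year, environment, trait)."""

    frame: pd.DataFrame = field(repr=False)

    KEY = ["line_id", "year", "environment", "trait"]

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.KEY + ["value"] if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        df = df.copy()
        df["year"] = df["year"].astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if not np.isfinite(df["value"].to_numpy(float)).all():
            raise ValueError("non-finite phenotype values")
        dup = df.duplicated(subset=self.KEY)
        if dup.any():
            key = df.loc[dup.idxmax(), self.KEY].tolist()
            raise ValueError(f"duplicate phenotype key {tuple(key)}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    def subset(
        self,
        year: int | None = None,
        environment: str | None = None,
        trait: str | None = None,
        lines: Sequence[str] | None = None,
        exclude_lines: Sequence[str] | None = None,
    ) -> "PhenotypeRecords":
        df = self.frame
        if year is not None:
            df = df[df["year"] == year]
        if environment is not None:
            df = df[df["environment"] == environment]
        if trait is not None:
            df = df[df["trait"] == trait]
        if lines is not None:
            df = df[df["line_id"].isin(set(lines))]
        if exclude_lines is not None:
            df = df[~df["line_id"].isin(set(exclude_lines))]
        return PhenotypeRecords(df.reset_index(drop=True))

    def series(self, year: int, environment: str, trait: str) -> pd.Series:
        """Phenotype values indexed by line_id for one (year, env, trait) cell."""
        df = self.subset(year=year, environment=environment, trait=trait).frame
        return df.set_index("line_id")["value"]


# ---------------------------------------------------------------------------
# panel loaders


def _finalize_matrix(
    mat: np.ndarray, line_ids: list[str], pred_ids: list[str], kind: str,
    chrom=None, pos=None, strict: bool = True,
) -> PredictorPanel:
    """Handle missing values / monomorphic columns, then build the panel."""
    mat = np.asarray(mat, dtype=float)
    n_missing = int(np.isnan(mat).sum())
    if n_missing:
        if strict:
            raise ValueError(f"{n_missing} missing genotype calls (strict mode)")
        col_mean = np.nanmean(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = np.rint(col_mean[idx[1]])
        logger.info("imputed %d missing genotype calls (column-mean, rounded)", n_missing)
    poly = mat.min(axis=0) != mat.max(axis=0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("dropped %d monomorphic predictors at load", n_mono)
        keep = np.where(poly)[0]
        mat = mat[:, keep]
        pred_ids = [pred_ids[i] for i in keep]
        chrom = None if chrom is None else np.asarray(chrom)[keep]
        pos = None if pos is None else np.asarray(pos)[keep]
    return PredictorPanel(line_ids, pred_ids, kind, mat, chrom=chrom, pos=pos)


def _read_vcf(path: Path, strict: bool) -> tuple:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    cols, ids, chroms, poss = [], [], [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())[:, :2]
        col = np.full(len(line_ids), np.nan)
        for i, (a0, a1) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                continue  # missing
            if a0 != a1:
                if strict:
                    raise ValueError(
                        f"heterozygous call for line {line_ids[i]!r} at "
                        f"{var.CHROM}:{var.POS} ({var.ID or '.'}); DH lines must be homozygous"
                    )
                col[i] = np.nan
            else:
                col[i] = float(a0 > 0)
        cols.append(col)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not cols:
        raise ValueError(f"no variants in {path}")
    return np.column_stack(cols), line_ids, ids, np.asarray(chroms), np.asarray(poss)


def _read_plink_raw(path: Path, strict: bool) -> tuple:
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in meta:
        raise ValueError(".raw file lacks an IID column")
    snp_cols = [c for c in df.columns if c not in meta]
    line_ids = df["IID"].astype(str).tolist()
    mat = df[snp_cols].to_numpy(dtype=float)
    bad = np.isin(mat[~np.isnan(mat)], [0.0, 2.0], invert=True)
    if bad.any():
        if strict:
            raise ValueError(
                "dosage 1 (heterozygous) or out-of-range values in .raw file; "
                "DH lines must have dosages in {0, 2}"
            )
        mat[np.isin(mat, [0.0, 2.0], invert=True) & ~np.isnan(mat)] = np.nan
    return mat / 2.0, line_ids, snp_cols, None, None


def _read_tsv_panel(path: Path, strict: bool) -> tuple:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy(dtype=float)
    ok = np.isnan(mat) | (mat == 0) | (mat == 1)
    if not ok.all():
        raise ValueError(f"TSV panel {path} contains values outside {{0,1}}")
    return mat, df.index.astype(str).tolist(), df.columns.astype(str).tolist(), None, None


def read_predictor_panel(
    path: str | Path,
    format: Literal["vcf", "plink_raw", "tsv"],
    kind: Literal["snp", "block"] = "snp",
    strict: bool = True,
) -> PredictorPanel:
    """Read a binary predictor panel.

    VCF homozygous calls recode 0/0 -> 0, 1/1 -> 1; PLINK ``.raw`` dosages
    {0, 2} halve to {0, 1}; TSV matrices must already be 0/1 with a line-id
    index column and predictor-id header.  In strict mode a heterozygous
    call or missing genotype is an error; in lenient mode missing calls are
    imputed to the rounded column mean (count logged) and heterozygous
    calls are treated as missing.  Monomorphic predictors are dropped with
    a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"vcf": _read_vcf, "plink_raw": _read_plink_raw, "tsv": _read_tsv_panel}
    if format not in readers:
        raise ValueError(f"unknown panel format {format!r}")
    mat, line_ids, pred_ids, chrom, pos = readers[format](path, strict)
    return _finalize_matrix(mat, line_ids, pred_ids, kind, chrom, pos, strict)


def write_panel(panel: PredictorPanel, path: str | Path) -> None:
    """Write a panel as a TSV matrix (lines x predictors)."""
    pd.DataFrame(
        panel.matrix, index=panel.line_ids, columns=panel.predictor_ids
    ).to_csv(path, sep="\t", index_label="line_id")


def read_phenotypes(path: str | Path) -> PhenotypeRecords:
    """Read a long-format phenotype TSV.

    Required header: line_id, year, environment, trait, value.  Rows whose
    value is missing/NA are dropped with a logged count (an unphenotyped
    line is legal); duplicate keys are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "environment": str, "trait": str})
    missing = [c for c in PhenotypeRecords.KEY + ["value"] if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table {path} missing columns {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    n_drop = int(df["value"].isna().sum())
    if n_drop:
        logger.info("dropped %d phenotype rows with missing values", n_drop)
        df = df[df["value"].notna()]
    return PhenotypeRecords(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# VIF-based LD pruning


def _vifs(sub: np.ndarray) -> np.ndarray:
    """VIF per column of a standardized window: diagonal of inv(corr)."""
    z = (sub - sub.mean(0)) / sub.std(0)
    r = (z.T @ z) / sub.shape[0]
    k = r.shape[0]
    # exact collinearity makes the correlation matrix singular -> infinite VIF;
    # compute per-column R^2 by least squares, which handles that case
    vifs = np.empty(k)
    for i in range(k):
        others = np.delete(np.arange(k), i)
        if others.size == 0:
            vifs[i] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(z[:, others], z[:, i], rcond=None)
        resid = z[:, i] - z[:, others] @ coef
        r2 = 1.0 - (resid @ resid) / (z[:, i] @ z[:, i])
        r2 = min(max(r2, 0.0), 1.0)
        vifs[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(
    panel: PredictorPanel,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> PredictorPanel:
    """Sliding-window VIF pruning (PLINK ``--indep``-style).

    Predictors are taken in map order (by chrom/pos when present, else input
    order).  Windows of ``window`` predictors advance by ``step`` over the
    original predictor positions; enumeration stops once a window reaches
    the end of the panel (the final window is truncated if it overruns).
    Within each window the predictor with the highest VIF among surviving
    predictors is removed iteratively until all VIFs are at or below the
    threshold; on ties the later predictor in map order is removed.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if vif_threshold <= 0:
        raise ValueError("vif_threshold must be positive")

    order = np.arange(panel.n_predictors)
    if panel.chrom is not None and panel.pos is not None:
        order = np.lexsort((np.asarray(panel.pos), np.asarray(panel.chrom)))
    mat = panel.matrix[:, order].astype(float)
    p = mat.shape[1]
    alive = np.ones(p, dtype=bool)

    start = 0
    while start < p:
        end = min(start + window, p)
        idx = np.where(alive[start:end])[0] + start
        while idx.size >= 2:
            sub = mat[:, idx]
            if (sub.min(0) == sub.max(0)).any():
                # zero-variance inside window (cannot occur after load-time
                # monomorphic drop, but guard): keep, VIF undefined
                keep = sub.min(0) != sub.max(0)
                idx = idx[keep]
                continue
            vifs = _vifs(sub)
            worst = np.max(vifs)
            if worst <= vif_threshold:
                break
            # tie -> later predictor in map order: argmax over reversed order
            cand = np.where(vifs == worst)[0]
            drop = idx[cand.max()]
            alive[drop] = False
            idx = idx[idx != drop]
        if end >= p:
            break
        start += step

    # preserve original input order of the kept predictors
    kept = np.sort(order[alive])
    logger.info("vif_prune kept %d of %d predictors", kept.size, p)
    return panel.subset_predictors(kept)


# ---------------------------------------------------------------------------
# kernel round-trip


def write_kernel(K, path: str | Path) -> None:
    """Write a relationship kernel as TSV with line-id header row and column."""
    pd.DataFrame(K.matrix, index=K.line_ids, columns=K.line_ids).to_csv(
        path, sep="\t", index_label="line_id", float_format="%.15g"
    )


def read_kernel(path: str | Path, kind: str = "gblup"):
    """Read a kernel TSV; rejects mismatched ids or asymmetry (> 1e-8)."""
    from .kernels import RelationshipKernel

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"kernel row/column ids mismatch in {path}")
    mat = df.to_numpy(dtype=float)
    dev = float(np.abs(mat - mat.T).max())
    if dev > 1e-8:
        raise ValueError(f"kernel in {path} is not symmetric (max |K - K^T| = {dev:.3g})")
    mat = 0.5 * (mat + mat.T)
    return RelationshipKernel(
        line_ids=list(df.index.astype(str)), matrix=mat, kind=kind,
        scale_c=math.nan, n_predictors_or_pairs=0,
    )
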