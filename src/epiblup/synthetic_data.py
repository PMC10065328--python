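"""Synthetic doubled-haploid panels and two-year phenotypes.

The generator emulates the structure of a DH landrace-derived panel:
fully homozygous 0/1 genotypes with block-structured LD (lines are
founder-haplotype mosaics with rare switch points, so nearby SNPs travel
together), a haplotype-block panel tagging the founder segments, and a
single trait measured in two years in several environments with tunable
per-year heritabilities, genetic correlation between years, additive plus
pairwise-epistatic architecture, and unbalanced phenotyping.

The two years' effect vectors are drawn jointly with correlation
``r_g_target`` (shared + year-specific components), so the genomic
correlation is induced at the effect level and per-year genetic variances
stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import PhenotypeRecords, PredictorPanel

__all__ = ["SimConfig", "SimTruth", "simulate_dh_panel", "simulate_two_year_phenotypes",
           "realized_parameters", "simulate_dataset"]


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults describe a small landrace-like DH panel: a few hundred lines,
    block LD from a handful of founders per region, a mostly additive
    trait with moderate epistasis, high genomic correlation between years
    and mild unbalancedness (nearly complete phenotyping in year 1, about
    a fifth of lines unphenotyped in year 2).
    """

    n_lines: int = 300
    p_snps: int = 500
    n_regions: int = 25
    n_founders_per_region: int = 4
    switch_rate: float = 0.02
    n_add_qtl: int = 100
    n_epi_pairs: int = 10
    epi_var_fraction: float = 0.2
    h2_year1: float = 0.7
    h2_year2: float = 0.6
    r_g_target: float = 0.9
    n_env: int = 1
    missing_frac_year1: float = 0.02
    missing_frac_year2: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "p_snps", "n_regions", "n_founders_per_region", "n_env"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate must be in [0, 1]")
        if not 0.0 <= self.epi_var_fraction <= 1.0:
            raise ValueError("epi_var_fraction must be in [0, 1]")
        if self.epi_var_fraction > 0 and self.n_epi_pairs == 0:
            raise ValueError("epi_var_fraction > 0 requires n_epi_pairs > 0")
        for name in ("h2_year1", "h2_year2"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if not -1.0 <= self.r_g_target <= 1.0:
            raise ValueError("r_g_target must be in [-1, 1]")


@dataclass
class SimTruth:
    """Ground truth stored alongside a simulated dataset."""

    qtl_idx: np.ndarray
    qtl_effects: np.ndarray          # (n_add_qtl, 2), one column per year
    epi_pairs: np.ndarray            # (n_epi_pairs, 2)
    epi_effects: np.ndarray          # (n_epi_pairs, 2)
    g: np.ndarray                    # (n_lines, 2) true genetic values
    realized_h2: tuple[float, float]
    realized_r_g: float
    realized_r_p: float
    block_founder: np.ndarray = field(default=None, repr=False)  # (n_lines, n_regions) majority founder


def simulate_dh_panel(config: SimConfig):
    """Simulate a DH SNP panel and its haplotype-block panel.

    Each region has ``n_founders_per_region`` founder haplotypes (0/1
    vectors with allele frequencies uniform on [0.1, 0.9]); each line is a
    Markov mosaic of founders along the region, switching founder between
    adjacent SNPs with probability ``switch_rate``.  The block panel has
    one column per (region, founder): the indicator that a line carries
    that founder over the majority of the region's span.

    Returns (snp_panel, block_panel, block_founder_matrix).
    """
    rng = np.random.default_rng(config.seed)
    n, nr = config.n_lines, config.n_regions
    nf = config.n_founders_per_region
    sizes = np.full(nr, config.p_snps // nr)
    sizes[: config.p_snps % nr] += 1

    snp_cols, snp_ids, chroms, poss = [], [], [], []
    block_cols, block_ids = [], []
    block_founder = np.empty((n, nr), dtype=int)
    for r in range(nr):
        m = sizes[r]
        freqs = rng.uniform(0.1, 0.9, size=m)
        founders = (rng.random((nf, m)) < freqs).astype(np.uint8)
        # founder identity chain per line
        ident = np.empty((n, m), dtype=int)
        ident[:, 0] = rng.integers(0, nf, size=n)
        for j in range(1, m):
            switch = rng.random(n) < config.switch_rate
            ident[:, j] = np.where(switch, rng.integers(0, nf, size=n), ident[:, j - 1])
        geno = founders[ident, np.arange(m)]
        snp_cols.append(geno)
        snp_ids.extend(f"r{r}_s{j}" for j in range(m))
        chroms.extend([r + 1] * m)
        poss.extend(range(1, m + 1))
        # majority founder over the region span
        counts = np.stack([(ident == f).sum(axis=1) for f in range(nf)], axis=1)
        maj = counts.argmax(axis=1)
        majority = counts[np.arange(n), maj] * 2 > m
        block_founder[:, r] = np.where(majority, maj, -1)
        for f in range(nf):
            block_cols.append((block_founder[:, r] == f).astype(np.uint8))
            block_ids.append(f"r{r}_f{f}")

    snp_mat = np.hstack(snp_cols)
    line_ids = [f"L{i:04d}" for i in range(n)]
    snp_panel = PredictorPanel(
        line_ids=line_ids, predictor_ids=snp_ids, kind="snp", matrix=snp_mat,
        chrom=np.asarray(chroms), pos=np.asarray(poss),
    )
    block_mat = np.column_stack(block_cols)
    # drop monomorphic block variants (a founder carried by no or all lines)
    poly = block_mat.min(axis=0) != block_mat.max(axis=0)
    block_panel = PredictorPanel(
        line_ids=line_ids,
        predictor_ids=[b for b, keep in zip(block_ids, poly) if keep],
        kind="block", matrix=block_mat[:, poly],
    )
    return snp_panel, block_panel, block_founder


def _correlated_effects(rng: np.random.Generator, m: int, rho: float) -> np.ndarray:
    """(m, 2) standard-normal effect pairs with across-year correlation rho."""
    shared = rng.standard_normal(m)
    spec = rng.standard_normal((m, 2))
    s = np.sign(rho) if rho < 0 else 1.0
    a = np.sqrt(abs(rho))
    b = np.sqrt(1.0 - abs(rho))
    out = np.empty((m, 2))
    out[:, 0] = a * shared + b * spec[:, 0]
    out[:, 1] = s * a * shared + b * spec[:, 1]
    return out


def simulate_two_year_phenotypes(panel: PredictorPanel, config: SimConfig):
    """Simulate two-year phenotype BLUEs on a simulated panel.

    Additive effects at ``n_add_qtl`` SNPs and interaction effects at
    ``n_epi_pairs`` random pairs are drawn jointly across years with
    correlation ``r_g_target``; the epistatic effect vectors are rescaled
    (one common factor, the geometric mean of the per-year exact factors)
    so the epistatic share of genetic variance is approximately
    ``epi_var_fraction``.  Per environment, residuals are scaled so the
    per-environment heritability matches ``h2_yearN``; a configurable
    fraction of lines is left unphenotyped per year.
    """
    rng = np.random.default_rng(config.seed + 1)
    m = panel.matrix.astype(float)
    n, p = m.shape
    if config.n_add_qtl > p:
        raise ValueError("more additive QTL than predictors")

    qtl = rng.choice(p, size=config.n_add_qtl, replace=False)
    a_eff = _correlated_effects(rng, config.n_add_qtl, config.r_g_target)
    z = m[:, qtl] - m[:, qtl].mean(axis=0)
    g_add = z @ a_eff  # (n, 2)

    if config.n_epi_pairs > 0:
        # causal interactions must segregate: keep pairs whose 1/1-combination
        # frequency is within [0.05, 0.95]
        pairs = []
        for _ in range(200 * config.n_epi_pairs):
            j, k = np.sort(rng.choice(p, size=2, replace=True))
            fr = float((panel.matrix[:, j] & panel.matrix[:, k]).mean())
            if 0.05 <= fr <= 0.95:
                pairs.append((j, k))
            if len(pairs) == config.n_epi_pairs:
                break
        else:
            raise ValueError("could not draw segregating epistatic pairs")
        pairs = np.asarray(pairs, dtype=int)
        e_eff = _correlated_effects(rng, config.n_epi_pairs, config.r_g_target)
        t = (panel.matrix[:, pairs[:, 0]] & panel.matrix[:, pairs[:, 1]]).astype(float)
        t -= t.mean(axis=0)
        g_epi = t @ e_eff
        f = config.epi_var_fraction
        if f > 0:
            va = g_add.var(axis=0)
            ve = g_epi.var(axis=0)
            if (ve <= 0).any():
                raise ValueError("epistatic component degenerate; choose other pairs/seed")
            scale = np.sqrt((f / (1.0 - f)) * va / ve) if f < 1 else np.sqrt(va / ve) * 1e6
            s = float(np.sqrt(scale[0] * scale[1]))  # common factor preserves r_g
            g_epi *= s
            e_eff = e_eff * s
        else:
            g_epi[:] = 0.0
            e_eff[:] = 0.0
    else:
        pairs = np.empty((0, 2), dtype=int)
        e_eff = np.empty((0, 2))
        g_epi = np.zeros((n, 2))

    g = g_add + g_epi
    h2 = (config.h2_year1, config.h2_year2)
    rows = []
    years = (1, 2)
    pheno_by_year = []
    for t_idx, yr in enumerate(years):
        vg = float(g[:, t_idx].var())
        se = np.sqrt(vg * (1.0 - h2[t_idx]) / h2[t_idx]) if h2[t_idx] < 1 else 0.0
        miss = (config.missing_frac_year1, config.missing_frac_year2)[t_idx]
        n_miss = int(round(miss * n))
        missing = set(rng.choice(n, size=n_miss, replace=False)) if n_miss else set()
        y_env0 = np.full(n, np.nan)
        for env in range(config.n_env):
            noise = rng.standard_normal(n) * se
            y = g[:, t_idx] + noise
            if env == 0:
                y_env0 = y
            for i, line in enumerate(panel.line_ids):
                if i in missing:
                    continue
                rows.append((line, yr, f"ENV{env + 1}", "trait", y[i]))
        pheno_by_year.append((y_env0, missing))

    records = PhenotypeRecords(
        pd.DataFrame(rows, columns=["line_id", "year", "environment", "trait", "value"])
    )
    r_g = float(np.corrcoef(g[:, 0], g[:, 1])[0, 1])
    both = [i for i in range(n)
            if i not in pheno_by_year[0][1] and i not in pheno_by_year[1][1]]
    r_p = float(np.corrcoef(pheno_by_year[0][0][both], pheno_by_year[1][0][both])[0, 1])
    realized_h2 = tuple(
        float(g[:, t].var() / pheno_by_year[t][0].var()) for t in range(2)
    )
    truth = SimTruth(
        qtl_idx=qtl, qtl_effects=a_eff, epi_pairs=pairs, epi_effects=e_eff,
        g=g, realized_h2=realized_h2, realized_r_g=r_g, realized_r_p=r_p,
    )
    return records, truth


def realized_parameters(records: PhenotypeRecords, truth: SimTruth) -> dict:
    """Recompute realized heritabilities and correlations from stored truth."""
    g = truth.g
    years = records.years
    out = {"r_g": float(np.corrcoef(g[:, 0], g[:, 1])[0, 1])}
    df = records.frame
    line_pos = {f"L{i:04d}": i for i in range(g.shape[0])}
    h2 = []
    for t_idx, yr in enumerate(years[:2]):
        sub = df[(df["year"] == yr) & (df["environment"] == df["environment"].iloc[0])]
        idx = np.array([line_pos[l] for l in sub["line_id"]])
        y = sub["value"].to_numpy(float)
        h2.append(float(g[idx, t_idx].var() / y.var()) if y.var() > 0 else 1.0)
    out["h2_year1"], out["h2_year2"] = h2[0], h2[1]
    env0 = df["environment"].iloc[0]
    a = df[(df["year"] == years[0]) & (df["environment"] == env0)].set_index("line_id")["value"]
    b = df[(df["year"] == years[1]) & (df["environment"] == env0)].set_index("line_id")["value"]
    common = a.index.intersection(b.index)
    out["r_p"] = float(np.corrcoef(a.loc[common], b.loc[common])[0, 1])
    return out


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: (snp_panel, block_panel, records, truth)."""
    snp_panel, block_panel, _ = simulate_dh_panel(config)
    records, truth = simulate_two_year_phenotypes(snp_panel, config)
    return snp_panel, block_panel, records, truth
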