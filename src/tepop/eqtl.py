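"""Cis-eQTL mapping of TE presence/absence against nearby gene expression.

Two passes, in the style of permutation-based cis-QTL mappers: a nominal pass
(Pearson correlation of covariate-residualized expression and genotype with
the exact t transform) and a permutation pass in which expression is permuted
across strains, the best nominal p over the gene's cis TEs is recorded per
permutation, a beta distribution is fitted to the permutation minima by
maximum likelihood, and the adjusted p is the fitted Beta CDF at the observed
best p.  Population structure is absorbed by regressing out covariates
(default: the leading principal components of the TE presence matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from tepop.io import GeneModel, RecombinationMap
from tepop.orthology import OrthologGroup
from tepop.presence import PresenceMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_N_PERM = 100_000
MIN_STRAINS = 6


# ---------------------------------------------------------------------------
# cis pairing and covariates
# ---------------------------------------------------------------------------


def build_cis_pairs(genes: list[GeneModel], groups: list[OrthologGroup],
                    window: int = DEFAULT_WINDOW) -> dict[str, list[str]]:
    """Map each gene to the TE groups whose interval intersects the gene span
    widened by ``window`` bp on both sides."""
    out: dict[str, list[str]] = {}
    for g in genes:
        lo, hi = g.start - window, g.end + window
        tes = [t.group_id for t in groups
               if t.chrom == g.chrom and t.start < hi and max(t.end, t.start + 1) > lo]
        if tes:
            out[g.gene_id] = tes
    return out


def presence_pcs(presence: PresenceMatrix, n_components: int = 2) -> np.ndarray:
    """Leading principal components of the centered presence matrix
    (strains x components) — the default population-structure covariates."""
    x = presence.data.values.astype(float)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, (s > 1e-12).sum())
    return u[:, :k] * s[:k]


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return v - v.mean()
    design = np.column_stack([np.ones(len(v)), covariates])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


# ---------------------------------------------------------------------------
# Nominal pass
# ---------------------------------------------------------------------------


def nominal_association(genotype: np.ndarray, expression: np.ndarray,
                        covariates: np.ndarray | None = None
                        ) -> tuple[float, float, float]:
    """(correlation, slope, nominal p) for one TE-gene pair.

    Both vectors are residualized on the covariates; p comes from the exact
    t transform of the Pearson correlation with degrees of freedom n - 2
    minus the covariate count.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(expression, dtype=float)
    n = len(g)
    if n < MIN_STRAINS:
        raise ValueError(f"need >= {MIN_STRAINS} strains, got {n}")
    if np.ptp(g) == 0:
        raise ValueError("constant genotype vector")
    if np.ptp(y) == 0:
        raise ValueError("constant expression vector")
    gr = _residualize(g, covariates)
    yr = _residualize(y, covariates)
    denom = np.sqrt((gr @ gr) * (yr @ yr))
    if denom == 0:
        raise ValueError("zero variance after residualization")
    r = float(np.clip((gr @ yr) / denom, -1.0, 1.0))
    slope = float((gr @ yr) / (gr @ gr))
    ncov = 0 if covariates is None else np.atleast_2d(covariates.T).shape[0]
    df = n - 2 - ncov
    p = _r_to_p(np.array([r]), df)[0]
    return r, slope, float(p)


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p from Pearson r via the t transform (vectorized)."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df)


# ---------------------------------------------------------------------------
# Permutation pass with beta approximation
# ---------------------------------------------------------------------------


@dataclass
class EqtlResult:
    gene_id: str
    te_id: str
    direction: str            # "up" | "down" with respect to TE presence
    r: float
    nominal_p: float
    beta_a: float
    beta_b: float
    adjusted_p: float
    empirical_p: float
    n_perm: int
    ties: list[str] = field(default_factory=list)


def fit_beta(x: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit on (0, 1) with method-of-moments
    start; falls back to the moment estimates if the optimizer fails."""
    x = np.clip(x, 1e-300, 1 - 1e-16)
    m, v = x.mean(), x.var()
    if v <= 0:
        return 1.0, 1.0
    common = m * (1 - m) / v - 1
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    lx, l1x = np.log(x).mean(), np.log1p(-x).mean()

    def nll(params):
        a, b = params
        return -(a - 1) * lx - (b - 1) * l1x + special.betaln(a, b)

    try:
        res = optimize.minimize(nll, [a0, b0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        a, b = res.x
        if res.success and a > 0 and b > 0:
            return float(a), float(b)
    except Exception:  # pragma: no cover - optimizer pathologies
        pass
    logger.warning("beta MLE failed; using method-of-moments estimates")
    return float(a0), float(b0)


def permutation_pass(gene_id: str, expression: np.ndarray,
                     cis_presence: pd.DataFrame,
                     covariates: np.ndarray | None = None,
                     n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                     min_perm: int = 100) -> EqtlResult:
    """Permutation-calibrated best association for one gene.

    ``cis_presence``: strains x cis-TE boolean frame.  Expression is permuted
    across strains ``n_perm`` times; the smallest nominal p over the gene's
    cis TEs per permutation forms the null sample for the beta fit.  TEs tied
    at the best nominal p are all reported.
    """
    if n_perm < min_perm:
        raise ValueError(f"n_perm={n_perm} too small for a stable beta fit "
                         f"(need >= {min_perm})")
    if cis_presence.shape[1] == 0:
        raise ValueError(f"gene {gene_id} has no cis TEs")
    rng = np.random.default_rng(seed)
    y = np.asarray(expression, dtype=float)
    n = len(y)
    geno = cis_presence.values.astype(float)
    usable = np.ptp(geno, axis=0) > 0
    if not usable.any():
        raise ValueError(f"gene {gene_id}: all cis genotype vectors constant")
    geno = geno[:, usable]
    te_ids = [t for t, u in zip(cis_presence.columns, usable) if u]

    gr = np.column_stack([_residualize(geno[:, j], covariates)
                          for j in range(geno.shape[1])])
    gr_norm = gr / np.linalg.norm(gr, axis=0)
    yr = _residualize(y, covariates)
    y_norm = yr / np.linalg.norm(yr)
    ncov = 0 if covariates is None else np.atleast_2d(covariates.T).shape[0]
    df = n - 2 - ncov

    r_obs = gr_norm.T @ y_norm
    p_obs = _r_to_p(r_obs, df)
    best = int(np.argmin(p_obs))
    p_best = float(p_obs[best])
    ties = [te_ids[j] for j in range(len(te_ids))
            if np.isclose(p_obs[j], p_best, rtol=1e-12, atol=0)]

    # permute residualized expression across strains, vectorized
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    y_perm = y_norm[perm_idx]                       # n_perm x n
    r_perm = y_perm @ gr_norm                       # n_perm x n_te
    p_min = _r_to_p(np.abs(r_perm).max(axis=1), df)

    a, b = fit_beta(p_min)
    adjusted = float(stats.beta.cdf(p_best, a, b))
    empirical = float((1 + (p_min <= p_best).sum()) / (n_perm + 1))
    direction = "up" if r_obs[best] > 0 else "down"
    return EqtlResult(gene_id, te_ids[best], direction, float(r_obs[best]),
                      p_best, a, b, adjusted, empirical, n_perm, ties)


def map_eqtls(expression: pd.DataFrame, presence: PresenceMatrix,
              genes: list[GeneModel], groups: list[OrthologGroup],
              covariates: np.ndarray | None = "pcs",
              window: int = DEFAULT_WINDOW, n_perm: int = DEFAULT_N_PERM,
              seed: int = 0) -> pd.DataFrame:
    """Run the full cis scan: pairing, nominal and permutation passes.

    ``covariates="pcs"`` uses the first two presence-matrix principal
    components; ``None`` disables structure correction.
    """
    strains = [s for s in expression.columns if s in set(presence.strains)]
    pm = presence.subset_strains(strains)
    if isinstance(covariates, str) and covariates == "pcs":
        covariates = presence_pcs(pm)
    cis = build_cis_pairs(genes, groups, window)
    gene_index = {g.gene_id: g for g in genes}
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(max(len(cis), 1)) % (2**31)
    for i, (gene_id, te_ids) in enumerate(sorted(cis.items())):
        if gene_id not in expression.index:
            continue
        y = expression.loc[gene_id, strains].values
        sub = pm.data[te_ids]
        try:
            res = permutation_pass(gene_id, y, sub, covariates, n_perm,
                                   seed=int(seeds[i]))
        except ValueError:
            continue
        rows.append({
            "gene_id": gene_id, "te_id": res.te_id, "direction": res.direction,
            "r": res.r, "nominal_p": res.nominal_p, "adjusted_p": res.adjusted_p,
            "empirical_p": res.empirical_p, "beta_a": res.beta_a,
            "beta_b": res.beta_b, "ties": ",".join(res.ties),
            "chrom": gene_index[gene_id].chrom if gene_id in gene_index else "",
        })
    return pd.DataFrame(rows)


def call_significant(results: pd.DataFrame, groups: list[OrthologGroup],
                     rec_map: RecombinationMap | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Keep associations with adjusted p strictly below ``alpha`` whose TE
    lies in a region of positive recombination."""
    by_id = {g.group_id: g for g in groups}
    keep = []
    for _, row in results.iterrows():
        if not row["adjusted_p"] < alpha:
            continue
        g = by_id.get(row["te_id"])
        if rec_map is not None and g is not None:
            try:
                rate = rec_map.rate_at(g.chrom, (g.start + g.end) // 2)
            except (KeyError, ValueError):
                continue
            if rate <= 0:
                continue
        keep.append(row)
    return pd.DataFrame(keep, columns=results.columns)
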