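"""Layer classification from parental-origin allele-specific counts.

The measurement design is a 2x2 factorial: one factor is the parental origin
of the transcript (lyc vs penn allele) and the other is the genome it was
measured in (parental wild type vs periclinal chimera).  Per gene and tissue
the four cells are

    Lw  lyc-allele counts in the lyc parent library,
    Pw  penn-allele counts in the penn parent library,
    Lc  lyc-allele counts in the chimera library,
    Pc  penn-allele counts in the chimera library.

In a chimera whose epidermis (L1) is penn and whose inner layers (L2/L3) are
lyc, a gene expressed only in L1 loses its lyc-allele signal in the chimera
(Lc collapses towards 0) while its penn-allele signal persists.  Four
treatment contrasts of a log-linear negative-binomial model capture this:

    a:  Lc vs Lw       (chimera effect on the lyc allele)
    b:  Pc vs Pw       (chimera effect on the penn allele)
    c:  interaction    (difference of the two chimera effects)
    d:  Pc vs Lc       (allelic imbalance within the chimera)

Each contrast is tested with a likelihood-ratio test of the saturated model
against the model with that one contrast constrained, p-values are FDR
adjusted per contrast across genes, and genes are classified per tissue as
L1/L2-L3 specific/related by the sign-and-significance rules implemented in
:func:`classify_gene`.  Multi-tissue evidence is merged by
:func:`combine_tissues`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

# Classification labels.
L1_SPECIFIC = "L1-specific"
L1_RELATED = "L1-related"
L2L3_SPECIFIC = "L2/L3-specific"
L2L3_RELATED = "L2/L3-related"
UNIFORM = "uniform"
UNCLASSIFIED = "unclassified"

LABELS = (L1_SPECIFIC, L1_RELATED, L2L3_SPECIFIC, L2L3_RELATED, UNCLASSIFIED)

#: Cell order used throughout: rows of the design matrix, count columns,
#: offset columns.
CELLS = ("Lw", "Pw", "Lc", "Pc")
OFFSET_COLS = ("off_lw", "off_pw", "off_lc", "off_pc")

#: Full-rank design for the saturated model, rows ordered as CELLS and
#: columns (intercept, origin=penn, genome=chimera, interaction).
X_FULL = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],  # Lw
        [1.0, 1.0, 0.0, 0.0],  # Pw
        [1.0, 0.0, 1.0, 0.0],  # Lc
        [1.0, 1.0, 1.0, 1.0],  # Pc
    ]
)

#: Contrast vectors c such that the tested quantity is c'beta.
CONTRASTS = {
    "a": np.array([0.0, 0.0, 1.0, 0.0]),  # log(mu_Lc / mu_Lw)
    "b": np.array([0.0, 0.0, 1.0, 1.0]),  # log(mu_Pc / mu_Pw)
    "c": np.array([0.0, 0.0, 0.0, 1.0]),  # interaction (log cross-ratio)
    "d": np.array([0.0, 1.0, 0.0, 1.0]),  # log(mu_Pc / mu_Lc)
}

_ETA_CLIP = 30.0


@dataclass
class ModelConfig:
    """Settings for the factorial NB model and the classification rules.

    dispersion_mode
        ``"fixed"`` uses ``dispersion_value`` for every gene;
        ``"common_estimated"`` replaces it with a cross-gene moment estimate
        computed under the reduced additive model.
    dispersion_value
        NB dispersion phi in Var = mu + phi * mu**2; phi = 0 is Poisson.
    fdr_method
        "BH" (Benjamini-Hochberg) or "BY" (Benjamini-Yekutieli).
    alpha
        FDR cut-off for calling a contrast significant.
    contrast_d_offset
        ``"none"`` tests Pc = Lc; ``"tissue_fraction"`` tests the allelic
        ratio against the tissue-composition expectation
        log(p_l1 / (1 - p_l1)), under which a uniformly expressed gene is
        null for contrast d.
    fdr_family
        "per_contrast" adjusts each contrast's p-values separately within a
        tissue (default); "global" pools all contrasts into one family.
    """

    dispersion_mode: str = "fixed"
    dispersion_value: float = 0.1
    fdr_method: str = "BH"
    alpha: float = 0.05
    contrast_d_offset: str = "none"
    p_l1: float = 0.2
    fdr_family: str = "per_contrast"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.dispersion_value < 0:
            raise ValueError("dispersion must be >= 0")
        if self.dispersion_mode not in ("fixed", "common_estimated"):
            raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")
        if self.fdr_method not in ("BH", "BY"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")
        if self.contrast_d_offset not in ("none", "tissue_fraction"):
            raise ValueError(f"unknown contrast_d_offset {self.contrast_d_offset!r}")
        if self.contrast_d_offset == "tissue_fraction" and not 0 < self.p_l1 < 1:
            raise ValueError("p_l1 must be in (0,1) for tissue_fraction mode")
        if self.fdr_family not in ("per_contrast", "global"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")

    def d_null_offset(self) -> float:
        if self.contrast_d_offset == "tissue_fraction":
            return math.log(self.p_l1 / (1.0 - self.p_l1))
        return 0.0


@dataclass
class ContrastResult:
    """LRT result for one contrast of one gene x tissue."""

    gene_id: str
    tissue: str
    contrast: str
    logFC: float
    stat: float
    p: float
    q: float = float("nan")


@dataclass
class GeneClassification:
    """Final multi-tissue layer call for one gene."""

    gene_id: str
    label: str
    supporting_tissues: frozenset = field(default_factory=frozenset)
    conflict: bool = False


# ---------------------------------------------------------------------------
# NB likelihood and batched IRLS
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Elementwise NB log-likelihood with Var = mu + phi*mu^2.

    phi = 0 degenerates to Poisson.  mu = 0 is allowed where y = 0 (the
    limit log-likelihood is 0 there).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(np.broadcast(y, mu).shape)
    pos = np.broadcast_to(mu, out.shape) > 0
    ymu = np.broadcast_arrays(y, mu)
    yb, mb = ymu[0], ymu[1]
    if phi == 0.0:
        out[pos] = (
            yb[pos] * np.log(mb[pos]) - mb[pos] - gammaln(yb[pos] + 1.0)
        )
    else:
        r = 1.0 / phi
        m = mb[pos]
        yy = yb[pos]
        out[pos] = (
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1.0)
            + r * np.log(r / (r + m))
            + yy * np.log(m / (r + m))
        )
    # mu == 0: loglik is 0 for y == 0 and -inf for y > 0
    zero_bad = (~pos) & (yb > 0)
    out[zero_bad] = -np.inf
    return out


def saturated_loglik(y: np.ndarray, phi: float) -> np.ndarray:
    """Log-likelihood of the saturated model (fitted means equal counts)."""
    y = np.asarray(y, dtype=float)
    return nb_loglik(y, y, phi).sum(axis=-1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    phi: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit log-linear NB GLMs by IRLS, batched over the leading axis.

    Parameters
    ----------
    y : (G, n) or (n,) counts
    X : (n, k) design matrix shared by all G fits
    offset : (G, n) or (n,) known log-scale offsets
    phi : fixed NB dispersion (0 = Poisson)

    Returns ``(beta, loglik)`` with shapes (G, k) and (G,).  One observation
    with a zero count in a cell that the reduced model fits exactly drives
    the linear predictor to the clip bound; the likelihood there is within
    rounding of its supremum, which is what the LRT needs.
    """
    y2 = np.atleast_2d(np.asarray(y, dtype=float))
    G, n = y2.shape
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    if offset is None:
        off = np.zeros((G, n))
    else:
        off = np.broadcast_to(np.asarray(offset, dtype=float), (G, n)).copy()

    # start from a least-squares fit on the log scale
    pinv = np.linalg.pinv(X)
    beta = (np.log(y2 + 0.5) - off) @ pinv.T

    eye = np.eye(k) * 1e-12
    ll_old = np.full(G, -np.inf)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = nb_loglik(y2, mu, phi).sum(axis=1)
        improved = np.abs(ll - ll_old) > tol * (np.abs(ll) + 1.0)
        active = active & improved
        if not active.any():
            break
        ll_old = ll
        w = mu / (1.0 + phi * mu) if phi > 0 else mu
        w = np.maximum(w, 1e-12)
        z = (eta - off) + (y2 - mu) / mu
        A = np.einsum("gi,ij,ik->gjk", w, X, X) + eye
        b = np.einsum("gi,ij,gi->gj", w, X, z)
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        beta[active] = beta_new[active]
    eta = np.clip(beta @ X.T + off, -_ETA_CLIP, _ETA_CLIP)
    ll = nb_loglik(y2, np.exp(eta), phi).sum(axis=1)
    return beta, ll


def _reduced_design(contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Reparameterize so the tested contrast is the last coefficient.

    Returns ``(X_reduced, x_test)`` where ``X_reduced`` (4x3) spans the null
    model {c'beta = 0} and ``x_test`` (4,) is the dropped column, used to
    inject a nonzero null value via the offset.
    """
    c = CONTRASTS[contrast]
    j = int(np.nonzero(c)[0][0])
    rows = [np.eye(4)[i] for i in range(4) if i != j]
    rows.append(c)
    T = np.array(rows)
    Xt = X_FULL @ np.linalg.inv(T)
    return Xt[:, :3], Xt[:, 3]


_REDUCED = {k: _reduced_design(k) for k in CONTRASTS}


# ---------------------------------------------------------------------------
# Saturated fit and contrast tests
# ---------------------------------------------------------------------------

def saturated_coefficients(
    counts: np.ndarray, offsets: np.ndarray | None = None
) -> np.ndarray:
    """Coefficients of the saturated model, batched over the leading axis.

    For all-positive cells these are exact maximum-likelihood values for any
    dispersion (the saturated fit reproduces the counts); when any cell is
    zero a +0.5 continuity correction is applied to all four cells so the
    log scale stays finite.  Used for reporting log-fold-changes, never for
    test statistics.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    G = y.shape[0]
    off = (
        np.zeros_like(y)
        if offsets is None
        else np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)
    )
    corr = (y == 0).any(axis=1, keepdims=True)
    y_adj = np.where(corr, y + 0.5, y)
    eta = np.log(y_adj) - off
    beta = eta @ np.linalg.inv(X_FULL).T
    return beta if np.asarray(counts).ndim == 2 else beta[0]


def fit_factorial_nb(
    counts: np.ndarray,
    config: ModelConfig | None = None,
    offsets: np.ndarray | None = None,
) -> dict:
    """Fit the saturated 2x2 factorial NB model to one gene x tissue.

    Returns a dict with the fitted means (equal to the counts), the
    coefficients (intercept, origin, genome, interaction) and the saturated
    log-likelihood.  Raises ``ValueError`` on an all-zero gene, which cannot
    be modelled and is skipped upstream.
    """
    config = config or ModelConfig()
    y = np.asarray(counts, dtype=float)
    if y.shape != (4,):
        raise ValueError("counts must be the four cells (Lw, Pw, Lc, Pc)")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if y.sum() == 0:
        raise ValueError("all four counts are zero; gene cannot be fitted")
    phi = config.dispersion_value if config.dispersion_mode == "fixed" else config.dispersion_value
    return {
        "fitted": y.copy(),
        "coefficients": saturated_coefficients(y, offsets),
        "loglik": float(saturated_loglik(y, phi)),
    }


def test_contrasts_batch(
    counts: np.ndarray,
    config: ModelConfig,
    offsets: np.ndarray | None = None,
    phi: float | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """LRTs of all four contrasts for a (G, 4) block of genes.

    Returns ``{contrast: {"logFC": ..., "stat": ..., "p": ...}}``.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    G = y.shape[0]
    off = (
        np.zeros_like(y)
        if offsets is None
        else np.broadcast_to(np.asarray(offsets, dtype=float), y.shape).copy()
    )
    if phi is None:
        phi = config.dispersion_value
    ll_sat = saturated_loglik(y, phi)
    beta_sat = saturated_coefficients(y, off)
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, c in CONTRASTS.items():
        Xr, x_test = _REDUCED[name]
        delta0 = config.d_null_offset() if name == "d" else 0.0
        off_r = off + delta0 * x_test
        _, ll_r = fit_nb_glm(y, Xr, off_r, phi)
        stat = np.maximum(2.0 * (ll_sat - ll_r), 0.0)
        p = chi2.sf(stat, df=1)
        logfc = beta_sat @ c - delta0
        out[name] = {"logFC": logfc, "stat": stat, "p": p}
    return out


def test_contrast(
    counts: np.ndarray,
    config: ModelConfig,
    contrast: str,
    offsets: np.ndarray | None = None,
    gene_id: str = "gene",
    tissue: str = "leaf",
) -> ContrastResult:
    """Single-gene convenience wrapper around :func:`test_contrasts_batch`."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of a, b, c, d")
    res = test_contrasts_batch(np.asarray(counts)[None, :], config, offsets)
    r = res[contrast]
    return ContrastResult(
        gene_id=gene_id,
        tissue=tissue,
        contrast=contrast,
        logFC=float(r["logFC"][0]),
        stat=float(r["stat"][0]),
        p=float(r["p"][0]),
    )


# these are statistical tests, not pytest cases
test_contrasts_batch.__test__ = False  # type: ignore[attr-defined]
test_contrast.__test__ = False  # type: ignore[attr-defined]


def adjust_fdr(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Step-up FDR q-values: BH, or BY with the harmonic-sum inflation."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    return multipletests(p, method=sm_method)[1]


def estimate_common_dispersion(
    counts: np.ndarray, offsets: np.ndarray | None = None
) -> float:
    """Common-dispersion estimate from the additive (no-interaction) model.

    The saturated 2x2 design leaves no residual degrees of freedom per
    gene, so phi is estimated across genes from the one residual degree of
    freedom each gene keeps under the additive Poisson fit, by equating the
    Pearson statistic to its degrees of freedom:

        sum_g sum_i (y_gi - mu_gi)^2 / (mu_gi (1 + phi mu_gi)) = G

    solved for phi >= 0 (0 when the data are under-dispersed).
    """
    from scipy.optimize import brentq

    y = np.atleast_2d(np.asarray(counts, dtype=float))
    keep = y.sum(axis=1) > 0
    y = y[keep]
    if y.shape[0] == 0:
        raise ValueError("no non-zero genes to estimate dispersion from")
    off = (
        np.zeros_like(y)
        if offsets is None
        else np.broadcast_to(np.asarray(offsets, dtype=float), y.shape)[keep]
    )
    Xr, _ = _REDUCED["c"]
    beta, _ = fit_nb_glm(y, Xr, off, phi=0.0)
    mu = np.exp(np.clip(beta @ Xr.T + off, -_ETA_CLIP, _ETA_CLIP))
    mu = np.maximum(mu, 1e-8)
    r2 = (y - mu) ** 2
    df = float(y.shape[0])  # one residual df per gene

    def pearson_gap(phi: float) -> float:
        return float((r2 / (mu * (1.0 + phi * mu))).sum() - df)

    if pearson_gap(0.0) <= 0.0:
        return 0.0
    hi = 1.0
    while pearson_gap(hi) > 0.0 and hi < 1e6:
        hi *= 10.0
    return float(brentq(pearson_gap, 0.0, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_gene(
    results: Mapping[str, ContrastResult] | Iterable[ContrastResult],
    config: ModelConfig | None = None,
) -> str:
    """Apply the sign-and-significance rules to one gene x tissue.

    L1-related: significant down-regulation of the lyc allele in the
    chimera (a), no significant *down*-regulation of the penn allele (b; a
    gene concentrated in the L1 layer legitimately rises in the penn
    channel), and a significant interaction (c).  L1-specific additionally
    requires penn dominance within the chimera (d, positive).  L2/L3 labels
    are the lyc/penn mirror image.
    """
    config = config or ModelConfig()
    if not isinstance(results, Mapping):
        results = {r.contrast: r for r in results}
    missing = [k for k in CONTRASTS if k not in results]
    if missing:
        raise ValueError(f"missing contrast result(s): {missing}")
    a, b, c, d = (results[k] for k in "abcd")
    alpha = config.alpha
    sig = lambda r: r.q <= alpha
    down = lambda r: sig(r) and r.logFC < 0
    if down(a) and not down(b) and sig(c):
        if sig(d) and d.logFC > 0:
            return L1_SPECIFIC
        return L1_RELATED
    if down(b) and not down(a) and sig(c):
        if sig(d) and d.logFC < 0:
            return L2L3_SPECIFIC
        return L2L3_RELATED
    return UNCLASSIFIED


def _layer(label: str) -> str | None:
    if label in (L1_SPECIFIC, L1_RELATED):
        return "L1"
    if label in (L2L3_SPECIFIC, L2L3_RELATED):
        return "L2/L3"
    return None


def combine_tissues(
    per_tissue: Mapping[str, str], gene_id: str = "gene"
) -> GeneClassification:
    """Merge per-tissue labels into one call.

    A layer call stands when at least one tissue supports it and no tissue
    supports the opposite layer; the specificity grade is the strongest
    among supporting tissues (specific beats related).  Tissues that call
    opposite layers yield unclassified with ``conflict=True``.
    """
    if not per_tissue:
        raise ValueError("no tissues to combine")
    layers = {t: _layer(lbl) for t, lbl in per_tissue.items()}
    called = {t: l for t, l in layers.items() if l is not None}
    if not called:
        return GeneClassification(gene_id, UNCLASSIFIED)
    distinct = set(called.values())
    if len(distinct) > 1:
        return GeneClassification(gene_id, UNCLASSIFIED, conflict=True)
    layer = distinct.pop()
    support = frozenset(called)
    specific = any(
        per_tissue[t] in (L1_SPECIFIC, L2L3_SPECIFIC) for t in support
    )
    if layer == "L1":
        label = L1_SPECIFIC if specific else L1_RELATED
    else:
        label = L2L3_SPECIFIC if specific else L2L3_RELATED
    return GeneClassification(gene_id, label, supporting_tissues=support)


def tissue_support_summary(
    classifications: Iterable[GeneClassification],
) -> pd.DataFrame:
    """Per tissue: share of classified genes it supports / solely supports."""
    classified = [c for c in classifications if c.label != UNCLASSIFIED]
    tissues: set[str] = set()
    for c in classified:
        tissues |= set(c.supporting_tissues)
    rows = []
    n = len(classified)
    for t in sorted(tissues):
        supported = sum(1 for c in classified if t in c.supporting_tissues)
        sole = sum(1 for c in classified if c.supporting_tissues == frozenset({t}))
        rows.append(
            {
                "tissue": t,
                "supported_fraction": supported / n if n else 0.0,
                "sole_fraction": sole / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "supported_fraction", "sole_fraction"])


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def classify_genes(
    counts: pd.DataFrame, config: ModelConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneClassification]]:
    """Run the full per-tissue analysis on a factorial counts table.

    Parameters
    ----------
    counts
        One row per gene x tissue with columns ``gene_id``, ``tissue``,
        ``Lw``, ``Pw``, ``Lc``, ``Pc``; optional per-cell log-offset columns
        ``off_lw``, ``off_pw``, ``off_lc``, ``off_pc`` and an ``expressed``
        flag (genes marked not expressed are skipped).

    Returns
    -------
    results : long DataFrame (gene, tissue, contrast, logFC, stat, p, q)
    per_tissue : DataFrame (gene, tissue, label)
    classifications : list of GeneClassification, one per gene
    """
    config = config or ModelConfig()
    required = {"gene_id", "tissue", *CELLS}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    df = counts.copy()
    if "expressed" in df.columns:
        df = df[df["expressed"].astype(bool)]
    totals = df[list(CELLS)].sum(axis=1)
    df = df[totals > 0]

    res_frames = []
    per_tissue_rows = []
    for tissue, block in df.groupby("tissue", sort=True):
        y = block[list(CELLS)].to_numpy(dtype=float)
        if all(c in block.columns for c in OFFSET_COLS):
            off = block[list(OFFSET_COLS)].to_numpy(dtype=float)
        else:
            off = None
        phi = config.dispersion_value
        if config.dispersion_mode == "common_estimated":
            phi = estimate_common_dispersion(y, off)
        tested = test_contrasts_batch(y, config, off, phi=phi)
        genes = block["gene_id"].to_numpy()
        if config.fdr_family == "global":
            pooled = np.concatenate([tested[k]["p"] for k in "abcd"])
            q_pooled = adjust_fdr(pooled, config.fdr_method)
            qs = {k: q_pooled[i * len(genes):(i + 1) * len(genes)] for i, k in enumerate("abcd")}
        else:
            qs = {k: adjust_fdr(tested[k]["p"], config.fdr_method) for k in "abcd"}
        for k in "abcd":
            res_frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "tissue": tissue,
                        "contrast": k,
                        "logFC": tested[k]["logFC"],
                        "stat": tested[k]["stat"],
                        "p": tested[k]["p"],
                        "q": qs[k],
                    }
                )
            )
        for i, g in enumerate(genes):
            per_gene = {
                k: ContrastResult(
                    g, tissue, k,
                    float(tested[k]["logFC"][i]),
                    float(tested[k]["stat"][i]),
                    float(tested[k]["p"][i]),
                    float(qs[k][i]),
                )
                for k in "abcd"
            }
            per_tissue_rows.append(
                {"gene_id": g, "tissue": tissue, "label": classify_gene(per_gene, config)}
            )

    results = (
        pd.concat(res_frames, ignore_index=True)
        if res_frames
        else pd.DataFrame(columns=["gene_id", "tissue", "contrast", "logFC", "stat", "p", "q"])
    )
    per_tissue = pd.DataFrame(per_tissue_rows, columns=["gene_id", "tissue", "label"])
    classifications = []
    if len(per_tissue):
        for gene, sub in per_tissue.groupby("gene_id", sort=True):
            labels = dict(zip(sub["tissue"], sub["label"]))
            classifications.append(combine_tissues(labels, gene_id=gene))
    return results, per_tissue, classifications
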