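"""Per-gene negative-binomial GLM likelihood-ratio contrasts.

Each gene is fit twice (full and nested reduced design) by IRLS with a
log link and per-sample library-size offsets; the statistic is
``lr = 2 (l_full - l_reduced)`` referred to a chi-square with
``df = rank(full) - rank(reduced)``. Dispersion is a per-gene
method-of-moments estimate floored at DISPERSION_FLOOR — a deliberate
simplification of shrinkage-based estimators, since downstream stages
consume only (lr, p, fdr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.linalg import lstsq, matrix_rank
from scipy.special import gammaln
from scipy.stats import chi2

from .types import DEResult, SampleMeta

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
_POISSON_ALPHA = 1e-8  # below this the Poisson likelihood is used


@dataclass
class ContrastSpec:
    """A nested pair of design matrices for one likelihood-ratio contrast."""

    name: str
    full: np.ndarray
    reduced: np.ndarray
    sex: str = ""

    def __post_init__(self) -> None:
        self.full = np.atleast_2d(np.asarray(self.full, dtype=float))
        self.reduced = np.atleast_2d(np.asarray(self.reduced, dtype=float))
        if self.full.shape[0] != self.reduced.shape[0]:
            raise ValueError("full and reduced designs must have equal row counts")
        if self.df < 1:
            raise ValueError(f"{self.name}: df must be >= 1")
        # nesting: every reduced column must lie in the full column space
        proj, *_ = lstsq(self.full, self.reduced, rcond=None)
        if not np.allclose(self.full @ proj, self.reduced, atol=1e-8):
            raise ValueError(f"{self.name}: reduced design not nested in full design")

    @property
    def df(self) -> int:
        return int(matrix_rank(self.full) - matrix_rank(self.reduced))

    @property
    def n_samples(self) -> int:
        return self.full.shape[0]


def group_design(labels) -> np.ndarray:
    """One-hot (cell-means) design matrix from group labels."""
    labels = list(labels)
    levels = sorted(set(labels))
    X = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        X[i, levels.index(lab)] = 1.0
    return X


def haplotype_anodev_spec(metas: list[SampleMeta], sex: str, nuc: str | None = None) -> tuple[ContrastSpec, list[str]]:
    """All-haplotypes-vs-common-mean deviance contrast within one sex.

    Returns the spec plus the sample ids it applies to (in order).
    """
    sel = [m for m in metas if m.sex == sex and (nuc is None or m.nuc == nuc)]
    if nuc is None:
        nucs = {m.nuc for m in sel}
        if len(nucs) > 1:
            nuc = sorted(nucs)[0]
            sel = [m for m in sel if m.nuc == nuc]
    full = group_design([m.mito for m in sel])
    reduced = np.ones((len(sel), 1))
    return ContrastSpec("haplotype", full, reduced, sex), [m.sample_id for m in sel]


def species_spec(
    metas: list[SampleMeta], sex: str, species_of: dict[str, str], nuc: str | None = None
) -> tuple[ContrastSpec, list[str]]:
    """Two-group contrast pooling haplotypes by species of origin (df=1)."""
    sel = [m for m in metas if m.sex == sex and (nuc is None or m.nuc == nuc)]
    if nuc is None:
        nucs = {m.nuc for m in sel}
        if len(nucs) > 1:
            nuc = sorted(nucs)[0]
            sel = [m for m in sel if m.nuc == nuc]
    full = group_design([species_of[m.mito] for m in sel])
    reduced = np.ones((len(sel), 1))
    return ContrastSpec("species", full, reduced, sex), [m.sample_id for m in sel]


def gxg_spec(
    metas: list[SampleMeta], sex: str, mitos: tuple[str, str], nucs: tuple[str, str]
) -> tuple[ContrastSpec, list[str]]:
    """Mitonuclear interaction: full = mito x nuc cell means, reduced = additive."""
    sel = [m for m in metas if m.sex == sex and m.mito in mitos and m.nuc in nucs]
    full = group_design([f"{m.mito}|{m.nuc}" for m in sel])
    mito_x = group_design([m.mito for m in sel])
    nuc_x = group_design([m.nuc for m in sel])
    reduced = np.hstack([np.ones((len(sel), 1)), mito_x[:, 1:], nuc_x[:, 1:]])
    return ContrastSpec("gxg", full, reduced, sex), [m.sample_id for m in sel]


# -- dispersion ------------------------------------------------------


def estimate_dispersion(row: np.ndarray, groups, offsets: np.ndarray | None = None) -> tuple[float, bool]:
    """Method-of-moments NB dispersion for one gene.

    Offset-normalized counts ``z = y / exp(offset)`` are pooled across
    groups: ``alpha = sum (n_g-1)(s2_g - mu_g) / sum (n_g-1) mu_g^2``,
    floored at DISPERSION_FLOOR. Returns (alpha, flagged) where flagged
    marks degenerate rows (all zero).
    """
    y = np.asarray(row, dtype=float)
    groups = np.asarray(groups)
    s = np.ones_like(y) if offsets is None else np.exp(np.asarray(offsets, dtype=float))
    z = y / s
    levels = np.unique(groups)
    sizes = np.array([(groups == g).sum() for g in levels])
    if not np.any(sizes >= 2):
        raise ValueError("dispersion needs >= 2 samples in some group")
    if np.all(y == 0):
        return DISPERSION_FLOOR, True
    num = 0.0
    den = 0.0
    for g in levels:
        zg = z[groups == g]
        if len(zg) < 2:
            continue
        mu = zg.mean()
        num += (len(zg) - 1) * (zg.var(ddof=1) - mu)
        den += (len(zg) - 1) * mu**2
    if den <= 0:
        return DISPERSION_FLOOR, True
    return max(num / den, DISPERSION_FLOOR), False


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups,
    offsets: np.ndarray | None = None,
    max_genes: int = 200,
) -> float:
    """Shared NB dispersion by Cox-Reid adjusted profile likelihood.

    Group means are profiled out with their (alpha-independent for
    equal within-group offsets) quasi-likelihood estimates; the CR
    adjustment ``-0.5 log det(X'WX)`` removes the plug-in bias that
    makes naive pooled moments anti-conservative. Uses up to
    ``max_genes`` moderately expressed genes.
    """
    groups = np.asarray(groups)
    y_all = counts.to_numpy(dtype=float)
    s = np.ones(y_all.shape[1]) if offsets is None else np.exp(np.asarray(offsets, float))
    totals = y_all.mean(axis=1)
    usable = np.flatnonzero(totals > 1)
    if len(usable) == 0:
        return DISPERSION_FLOOR
    if len(usable) > max_genes:
        # deterministic spread across the expression range
        order = usable[np.argsort(totals[usable])]
        usable = order[np.linspace(0, len(order) - 1, max_genes).astype(int)]
    Y = y_all[usable]
    levels = np.unique(groups)
    group_masks = [groups == g for g in levels]
    # plug-in group means on the offset scale: mu_g = sum y / sum s
    MU = np.empty_like(Y)
    for mask in group_masks:
        mu = Y[:, mask].sum(axis=1) / s[mask].sum()
        MU[:, mask] = np.outer(mu, s[mask])
    MU = np.maximum(MU, 1e-8)

    def neg_apl(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        r = 1.0 / alpha
        ll = (
            gammaln(Y + r) - gammaln(r) - gammaln(Y + 1)
            + Y * np.log(alpha * MU / (1 + alpha * MU))
            - r * np.log1p(alpha * MU)
        ).sum()
        W = MU / (1.0 + alpha * MU)
        adj = 0.0
        for mask in group_masks:
            adj += 0.5 * np.log(W[:, mask].sum(axis=1)).sum()
        return -(ll - adj)

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_apl, bounds=(np.log(1e-6), np.log(20.0)), method="bounded")
    return max(float(np.exp(res.x)), DISPERSION_FLOOR)


# -- NB GLM fitting --------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha <= _POISSON_ALPHA:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - r * np.log1p(alpha * mu)
        )
    )


def _fit_nb_glm(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
    max_iter: int = 100, tol: float = 1e-10,
) -> tuple[float, bool]:
    """IRLS fit of an NB (log link) GLM; returns (loglik, converged).

    A half-count pseudocount initialization keeps log() finite; eta is
    clipped to avoid overflow on wild steps.
    """
    y = np.asarray(y, dtype=float)
    beta, *_ = lstsq(X, np.log(y + 0.5) - offset, rcond=None)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        ll = _nb_loglik(np.maximum(y, 0), np.maximum(mu, 1e-300), alpha)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            break
        ll_old = ll
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            beta, *_ = lstsq(X * np.sqrt(w)[:, None], np.sqrt(w) * z, rcond=None)
    eta = np.clip(X @ beta + offset, -30, 30)
    return _nb_loglik(y, np.exp(eta), alpha), converged


def lrt_contrast(
    row: np.ndarray,
    spec: ContrastSpec,
    offsets: np.ndarray | None = None,
    dispersion: float = DISPERSION_FLOOR,
    gene_id: str = "",
) -> DEResult:
    """Likelihood-ratio test of ``spec.full`` against ``spec.reduced`` for one gene."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    y = np.asarray(row, dtype=float)
    if len(y) != spec.n_samples:
        raise ValueError("row length does not match design")
    off = np.zeros_like(y) if offsets is None else np.asarray(offsets, dtype=float)
    alpha = max(dispersion, 0.0)
    ll_full, ok_full = _fit_nb_glm(y, spec.full, off, alpha)
    ll_red, ok_red = _fit_nb_glm(y, spec.reduced, off, alpha)
    lr = max(0.0, 2.0 * (ll_full - ll_red))
    if ok_full and ok_red:
        p = float(chi2.sf(lr, spec.df)) if lr > 0 else 1.0
        converged = True
    else:
        p = float("nan")
        converged = False
    return DEResult(gene_id or "gene", spec.name, spec.sex, lr, spec.df, p,
                    converged=converged)


def library_size_offsets(counts: pd.DataFrame) -> np.ndarray:
    """log library-size offsets, centered so the geometric mean factor is 1."""
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(libs <= 0):
        raise ValueError("every sample must have positive library size")
    off = np.log(libs)
    return off - off.mean()


def filter_low_counts(counts: pd.DataFrame, min_count: float = 5, min_samples: int | None = None) -> pd.DataFrame:
    """Drop genes expressed below ``min_count`` in fewer than ``min_samples`` samples.

    The default rule is logged; the threshold is configurable because the
    upstream convention is not fixed.
    """
    if min_samples is None:
        min_samples = max(2, counts.shape[1] // 4)
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("low-count filter dropped %d/%d genes (min_count=%s, min_samples=%d)",
                    n_drop, len(counts), min_count, min_samples)
    return counts.loc[keep]


def run_contrast(
    counts: pd.DataFrame,
    sample_ids: list[str],
    spec: ContrastSpec,
    dispersions: pd.Series | None = None,
    dispersion_mode: str = "shrunk",
    shrink_weight: float = 0.15,
) -> pd.DataFrame:
    """Apply ``lrt_contrast`` to every gene; returns a tidy DE table with FDR.

    Dispersion handling (unless explicit per-gene ``dispersions`` are
    given): 'per-gene' uses the raw method-of-moments estimate, 'common'
    uses one CR-adjusted profile-likelihood estimate for all genes, and
    'shrunk' (default) blends the two —
    ``shrink_weight * per_gene + (1 - shrink_weight) * common`` — which
    keeps type-I error calibrated at small replicate counts while
    letting strongly overdispersed genes stand out.
    """
    if dispersion_mode not in {"per-gene", "common", "shrunk"}:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    sub = counts[sample_ids]
    off = library_size_offsets(sub)
    group_keys = [tuple(r) for r in spec.full]
    groups = np.array([group_keys.index(k) for k in group_keys])
    common = None
    if dispersions is None and dispersion_mode in {"common", "shrunk"}:
        common = estimate_common_dispersion(sub, groups, off)
    rows = []
    n_bad = 0
    for gid, row in zip(sub.index, sub.to_numpy()):
        if dispersions is not None:
            alpha = float(dispersions[gid])
        elif dispersion_mode == "common":
            alpha = common
        else:
            alpha, _ = estimate_dispersion(row, groups, off)
            if dispersion_mode == "shrunk":
                alpha = shrink_weight * alpha + (1 - shrink_weight) * common
        res = lrt_contrast(row, spec, off, alpha, gene_id=gid)
        if not res.converged:
            n_bad += 1
        rows.append(res)
    if n_bad:
        logger.warning("%d/%d genes failed to converge in contrast %s",
                       n_bad, len(rows), spec.name)
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "contrast": spec.name,
            "sex": spec.sex,
            "lr": [r.lr for r in rows],
            "df": spec.df,
            "p_value": [r.p_value for r in rows],
        }
    )
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    return df


# -- multiplicity and ranking ----------------------------------------


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaNs are excluded and reinserted."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def top_n_by_pvalue(results: pd.DataFrame, n: int) -> list[str]:
    """Gene ids of the ``n`` smallest p-values; ties break lexicographically."""
    if n <= 0:
        raise ValueError("n must be positive")
    usable = results.dropna(subset=["p_value"])
    if n > len(usable):
        raise ValueError(f"requested top {n} of only {len(usable)} results")
    ordered = usable.sort_values(["p_value", "gene_id"], kind="stable")
    return ordered["gene_id"].head(n).tolist()
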