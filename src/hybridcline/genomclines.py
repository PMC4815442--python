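"""Genomic clines: locus-specific genotype probabilities vs hybrid index.

For a bi-allelic locus the three genotype classes are EE (homozygous for the
Engelmann-representative allele), WE (heterozygous) and WW.  Under neutral
admixture an individual with hybrid index h draws each allele copy E with
probability q = h p_E + (1 - h) p_W, giving Hardy-Weinberg genotype
probabilities (q^2, 2q(1-q), (1-q)^2).  Observed genotypes are fitted with a
multinomial logistic regression on (h, h^2); the improvement of the fit over
the neutral expectation is compared against a parametric null built by
simulating genotypes from the neutral probabilities B times ("1000
permutations" in the field's usage).  Loci whose fitted curves escape the
pointwise 95% neutral envelope are classified into selection modes:
directional selection toward a parental species (EE+/-, WW+/-), over- or
underdominance (WE+/-), or epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import DELTA_MIN, ParentalReference
from .io import MISSING, GenotypeMatrix

#: hybrid-index grid on which fitted curves and envelopes are reported
H_GRID = np.linspace(0.0, 1.0, 101)

#: genotype-class order used throughout this module
CLASSES = ("EE", "WE", "WW")

MODES = ("neutral", "EE+", "EE-", "WW+", "WW-", "WE+", "WE-", "epistasis")


def neutral_genotype_probs(h, p_e, p_w):
    """Neutral-admixture genotype probabilities (P_EE, P_WE, P_WW).

    ``h`` may be scalar or array; the allele is oriented so that p_E >= p_W.
    """
    h = np.asarray(h, dtype=float)
    q = h * p_e + (1.0 - h) * p_w
    return np.stack([q * q, 2.0 * q * (1.0 - q), (1.0 - q) ** 2], axis=-1)


# ---------------------------------------------------------------------------
# Multinomial logistic fit (quadratic in h), hand-rolled Newton solver:
# it runs ~10^5 times inside permutation nulls, so it is kept allocation-lean.
# ---------------------------------------------------------------------------

#: clamp for the logit transform of the hybrid index (parental h = 0 or 1)
_H_EPS = 1e-3


def _design(h):
    """Regression basis: intercept plus quadratic in logit(h).

    On the logit scale the neutral-admixture genotype logits are linear in
    logit(q) (for a diagnostic locus exactly 2*logit(h) and logit(h) + log 2),
    so this basis can represent the neutral model itself; the quadratic term
    lets individual classes (notably heterozygotes) bend away from it.
    """
    h = np.clip(np.asarray(h, dtype=float), _H_EPS, 1.0 - _H_EPS)
    u = np.log(h / (1.0 - h))
    return np.column_stack([np.ones_like(u), u, u * u])


def _softmax3(eta):
    # eta: (n, 2) linear predictors for classes EE, WE against reference WW
    m = np.maximum(eta.max(axis=1), 0.0)
    e = np.exp(eta - m[:, None])
    e0 = np.exp(-m)
    denom = e.sum(axis=1) + e0
    p = np.empty((eta.shape[0], 3))
    p[:, :2] = e / denom[:, None]
    p[:, 2] = e0 / denom
    return p


def _nll_probs(X, B, Y, ridge):
    P = _softmax3(X @ B)
    nll = -np.log(np.maximum((P * Y).sum(axis=1), 1e-300)).sum() \
        + 0.5 * ridge * (B * B).sum()
    return nll, P


def _fit_multinomial(X, Y, ridge=1e-8, max_iter=30, grad_tol=1e-6):
    """Damped-Newton fit of a 3-class multinomial logit (reference class WW).

    ``X`` is the (n, 3) design, ``Y`` the (n, 3) one-hot genotype classes in
    the order EE, WE, WW.  Returns (coef (3, 2), logL, converged).
    """
    B = np.zeros((3, 2))
    Y2 = Y[:, :2]
    nll, P = _nll_probs(X, B, Y, ridge)
    converged = False
    eye2 = np.eye(2)
    for _ in range(max_iter):
        g = X.T @ (P[:, :2] - Y2) + ridge * B  # (3, 2)
        if np.abs(g).max() < grad_tol:
            converged = True
            break
        # weights w[n, a, b] = p_a (delta_ab - p_b) over non-reference classes
        P2 = P[:, :2]
        Wt = P2[:, :, None] * (eye2[None] - P2[:, None, :])
        H = np.einsum("ni,nab,nj->aibj", X, Wt, X).reshape(6, 6)
        H[np.diag_indices(6)] += ridge
        try:
            step = np.linalg.solve(H, g.T.ravel()).reshape(2, 3).T
        except np.linalg.LinAlgError:
            step = g
        scale = 1.0
        for _ in range(12):
            B_new = B - scale * step
            nll_new, P_new = _nll_probs(X, B_new, Y, ridge)
            if nll_new <= nll + 1e-12:
                break
            scale *= 0.5
        if not np.isfinite(nll_new):
            break
        B, nll, P = B_new, nll_new, P_new
    logl = float(np.log(np.maximum((P * Y).sum(axis=1), 1e-300)).sum())
    return B, logl, converged


def _fit_multinomial_batch(X, Ys, ridge=1e-8, max_iter=30, grad_tol=1e-5):
    """Newton fit of many 3-class multinomial logits sharing one design.

    ``Ys`` is a (B, n, 3) stack of one-hot responses.  Vectorizes the
    per-replicate Newton iterations of :func:`_fit_multinomial` across the
    batch (the workhorse of the permutation null).  Returns
    (coefs (B, 3, 2), logL (B,)).
    """
    Bn, n, _ = Ys.shape
    coef = np.zeros((Bn, 3, 2))
    active = np.ones(Bn, dtype=bool)
    Y2 = Ys[:, :, :2]

    def eval_nll(c):
        eta = np.einsum("ni,bik->bnk", X, c)
        m = np.maximum(eta.max(axis=2), 0.0)
        e = np.exp(eta - m[:, :, None])
        e0 = np.exp(-m)
        denom = e.sum(axis=2) + e0
        P = np.empty((Bn, n, 3))
        P[:, :, :2] = e / denom[:, :, None]
        P[:, :, 2] = e0 / denom
        nll = -np.log(np.maximum((P * Ys).sum(axis=2), 1e-300)).sum(axis=1) \
            + 0.5 * ridge * (c * c).sum(axis=(1, 2))
        return nll, P

    nll, P = eval_nll(coef)
    idx6 = np.arange(6)
    for _ in range(max_iter):
        resid = P[:, :, :2] - Y2
        g = np.einsum("ni,bna->bai", X, resid)            # (B, 2, 3)
        gmax = np.abs(g).max(axis=(1, 2))
        active &= gmax > grad_tol
        if not active.any():
            break
        w00 = P[:, :, 0] * (1.0 - P[:, :, 0])
        w11 = P[:, :, 1] * (1.0 - P[:, :, 1])
        w01 = -P[:, :, 0] * P[:, :, 1]
        H = np.empty((Bn, 6, 6))
        H[:, :3, :3] = np.einsum("bn,ni,nj->bij", w00, X, X)
        H[:, 3:, 3:] = np.einsum("bn,ni,nj->bij", w11, X, X)
        H[:, :3, 3:] = np.einsum("bn,ni,nj->bij", w01, X, X)
        H[:, 3:, :3] = H[:, :3, 3:]
        H[:, idx6, idx6] += ridge
        try:
            step = np.linalg.solve(H, g.reshape(Bn, 6)[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = g.reshape(Bn, 6).copy()
        step = step.reshape(Bn, 2, 3).transpose(0, 2, 1)   # (B, 3, 2)
        step[~active] = 0.0
        scale = np.ones(Bn)
        for _ in range(8):
            cand = coef - scale[:, None, None] * step
            nll_new, P_new = eval_nll(cand)
            worse = active & (nll_new > nll + 1e-12)
            if not worse.any():
                break
            scale[worse] *= 0.5
        improved = active & (nll_new <= nll + 1e-12)
        coef[improved] = cand[improved]
        nll[improved] = nll_new[improved]
        P[improved] = P_new[improved]
        active &= improved
    logl = np.log(np.maximum((P * Ys).sum(axis=2), 1e-300)).sum(axis=1)
    return coef, logl


def _one_hot(dosage_e):
    """Map E-allele dosage (0/1/2) to one-hot classes (EE, WE, WW)."""
    d = np.asarray(dosage_e)
    Y = np.zeros((d.size, 3))
    Y[d == 2, 0] = 1.0
    Y[d == 1, 1] = 1.0
    Y[d == 0, 2] = 1.0
    return Y


@dataclass
class GenotypeClineFit:
    """Fitted genotype-probability curves for one locus."""

    coef: np.ndarray          # (3 features, 2 classes)
    log_likelihood: float
    curves: np.ndarray        # (len(H_GRID), 3) probabilities per class
    deviance: float | None    # -2 (logL_neutral - logL_fit) when reference given
    flagged: bool = False
    flag_reason: str = ""


def fit_genotype_cline(dosage_e, h, p_e: float | None = None,
                       p_w: float | None = None, ridge: float = 1e-8,
                       min_n: int = 30) -> GenotypeClineFit:
    """Multinomial regression of genotype class on (h, h^2).

    ``dosage_e`` counts E alleles (0/1/2) per individual.  When the parental
    frequencies are given, the returned deviance is the fit's improvement
    over the neutral-admixture log-likelihood.  Degenerate data (fewer than
    two observed classes) and separated fits are flagged; separation is
    re-fitted with a stabilizing ridge.
    """
    d = np.asarray(dosage_e)
    h = np.asarray(h, dtype=float)
    keep = d != MISSING
    d, h = d[keep], h[keep]
    if d.size < min_n:
        raise ValueError(f"need >= {min_n} individuals with genotype and h")
    Y = _one_hot(d)
    observed = Y.sum(axis=0) > 0

    neutral_ll = None
    if p_e is not None and p_w is not None:
        pn = np.clip(neutral_genotype_probs(h, p_e, p_w), 1e-12, 1.0)
        neutral_ll = float(np.log((pn * Y).sum(axis=1)).sum())

    if observed.sum() < 2:
        share = Y.mean(axis=0)
        curves = np.tile(share, (H_GRID.size, 1))
        logl = float(np.log(np.maximum((share * Y).sum(axis=1), 1e-300)).sum())
        dev = None if neutral_ll is None else -2.0 * (neutral_ll - logl)
        return GenotypeClineFit(coef=np.zeros((3, 2)), log_likelihood=logl,
                                curves=curves, deviance=dev, flagged=True,
                                flag_reason="degenerate: single genotype class")

    X = _design(h)
    B, logl, converged = _fit_multinomial(X, Y, ridge=ridge)
    flagged, reason = False, ""
    if not converged or np.abs(B).max() > 50.0:
        B, logl, _ = _fit_multinomial(X, Y, ridge=1e-2)
        flagged, reason = True, "separation: ridge-stabilized fit"
    curves = _softmax3(_design(H_GRID) @ B)
    dev = None if neutral_ll is None else -2.0 * (neutral_ll - logl)
    return GenotypeClineFit(coef=B, log_likelihood=logl, curves=curves,
                            deviance=dev, flagged=flagged, flag_reason=reason)


@dataclass
class GenomicClineResult:
    """Permutation-calibrated genomic cline for one locus."""

    locus: str
    fit: GenotypeClineFit
    p_value: float
    envelope_low: np.ndarray   # (len(H_GRID), 3)
    envelope_high: np.ndarray
    observed_stat: float
    n_permutations: int
    mode: str = "unclassified"
    fst: float = float("nan")
    h_grid: np.ndarray = field(default_factory=lambda: H_GRID.copy())


def permutation_test(dosage_e, h, p_e: float, p_w: float, B: int = 1000,
                     seed=None, rng=None, locus: str = "",
                     ridge: float = 1e-8) -> GenomicClineResult:
    """Parametric neutral null for one locus.

    Simulates ``B`` neutral replicates (each individual's genotype drawn from
    its neutral probabilities given h), refits the multinomial model on each,
    and compares the observed statistic -2 (logL_neutral - logL_fit) against
    the replicate distribution: p = (1 + #{replicate >= observed}) / (B + 1).
    Pointwise 2.5%/97.5% quantiles of the replicate curves form the neutral
    envelope per genotype class.
    """
    import warnings as _warnings
    if B < 100:
        _warnings.warn(f"B={B} permutations give coarse p-value resolution")
    if rng is None:
        rng = np.random.default_rng(seed)
    d = np.asarray(dosage_e)
    h = np.asarray(h, dtype=float)
    keep = d != MISSING
    d, h = d[keep], h[keep]

    obs_fit = fit_genotype_cline(d, h, p_e, p_w, ridge=ridge)
    t_obs = obs_fit.deviance

    probs = neutral_genotype_probs(h, p_e, p_w)          # (n, 3) EE, WE, WW
    cum = np.cumsum(probs, axis=1)
    X = _design(h)
    n = h.size
    Xg = _design(H_GRID)
    log_pn = np.log(np.clip(probs, 1e-12, 1.0))

    u = rng.random((B, n))
    cls = (u[:, :, None] > cum[None]).sum(axis=2)        # 0=EE, 1=WE, 2=WW
    Ys = np.zeros((B, n, 3))
    b_idx = np.repeat(np.arange(B), n)
    Ys[b_idx, np.tile(np.arange(n), B), cls.ravel()] = 1.0

    coefs, logls = _fit_multinomial_batch(X, Ys, ridge=ridge)
    neutral_lls = np.einsum("nk,bnk->b", log_pn, Ys)
    stats_null = -2.0 * (neutral_lls - logls)
    curves_null = np.empty((B, H_GRID.size, 3))
    for b in range(B):
        curves_null[b] = _softmax3(Xg @ coefs[b])
    degenerate = Ys.sum(axis=1).max(axis=1) == n          # all one class
    if degenerate.any():
        stats_null[degenerate] = 0.0
        curves_null[degenerate] = Ys[degenerate].mean(axis=1)[:, None, :]
    p = (1.0 + np.sum(stats_null >= t_obs)) / (B + 1.0)
    lo = np.quantile(curves_null, 0.025, axis=0)
    hi = np.quantile(curves_null, 0.975, axis=0)
    return GenomicClineResult(locus=locus, fit=obs_fit, p_value=float(p),
                              envelope_low=lo, envelope_high=hi,
                              observed_stat=float(t_obs), n_permutations=B)


def classify_selection(result: GenomicClineResult, alpha: float = 1e-4,
                       excursion_frac: float = 0.2,
                       interior=(0.1, 0.9)) -> str:
    """Classify the mode of selection from envelope excursions.

    Loci with p >= alpha are neutral.  Otherwise, for each genotype class the
    fraction of the interior hybrid-index grid (default h in (0.1, 0.9))
    where the fitted curve exits the neutral envelope is measured in each
    direction.  A class escaping upward (downward) over at least
    ``excursion_frac`` of the interior grid and carrying the largest
    integrated excursion area gives EE+/-, WE+/- (over/underdominance) or
    WW+/-; a single homozygote class escaping upward while both other
    classes stay inside everywhere is reported as epistasis.
    """
    if result.p_value >= alpha:
        result.mode = "neutral"
        return result.mode
    inside_interior = (H_GRID > interior[0]) & (H_GRID < interior[1])
    curves = result.fit.curves
    up = curves > result.envelope_high
    down = curves < result.envelope_low
    up_frac = up[inside_interior].mean(axis=0)
    down_frac = down[inside_interior].mean(axis=0)
    up_area = np.where(up, curves - result.envelope_high, 0.0)[inside_interior].sum(axis=0)
    down_area = np.where(down, result.envelope_low - curves, 0.0)[inside_interior].sum(axis=0)

    # epistasis: exactly one homozygote exits upward, everything else inside
    exits_any = (up | down).any(axis=0)
    homo_up = [up_frac[i] > 0 for i in (0, 2)]
    if sum(homo_up) == 1:
        k = 0 if homo_up[0] else 2
        others = [i for i in range(3) if i != k]
        if up_frac[k] >= excursion_frac and down_frac[k] == 0 \
                and not any(exits_any[i] for i in others):
            result.mode = "epistasis"
            return result.mode

    candidates = []
    for i, name in enumerate(CLASSES):
        if up_frac[i] >= excursion_frac:
            candidates.append((up_area[i], f"{name}+"))
        if down_frac[i] >= excursion_frac:
            candidates.append((down_area[i], f"{name}-"))
    if not candidates:
        result.mode = "neutral"
        return result.mode
    result.mode = max(candidates)[1]
    return result.mode


def climate_association(genotype_class, climate, min_per_class: int = 5):
    """Kruskal-Wallis rank test of a climate variable across genotype classes.

    Returns (H statistic, p).  Requires at least two classes with
    ``min_per_class`` individuals each.
    """
    genotype_class = np.asarray(genotype_class)
    climate = np.asarray(climate, dtype=float)
    groups = []
    for cls in np.unique(genotype_class):
        vals = climate[genotype_class == cls]
        if vals.size >= min_per_class:
            groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least two genotype classes with "
                         f">= {min_per_class} individuals")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Per-panel driver
# ---------------------------------------------------------------------------

def run_genomic_clines(gm: GenotypeMatrix, h, ref: ParentalReference,
                       B: int = 1000, seed=None, alpha: float = 1e-4,
                       delta_min: float = DELTA_MIN,
                       pops_w=None, pops_e=None):
    """Genomic cline analysis over all bi-allelic loci of a panel.

    Loci whose parental frequency differential |p_E - p_W| is below
    ``delta_min`` are excluded (too little differentiation to estimate a
    cline).  When the parental panel populations are given, each locus also
    gets its Weir-Cockerham F_st between the panels.  Returns
    (table, results): a per-locus DataFrame with p-value, selection mode and
    parental-panel F_st, plus the full result objects.
    """
    from .diversity import fst_between_panels

    rng = np.random.default_rng(seed)
    h = np.asarray(h, dtype=float)
    rows, results = [], []
    for j, locus in enumerate(gm.loci):
        if gm.marker_class[j] != "SNP":
            raise ValueError("genomic clines accept only bi-allelic (SNP) input")
        p_w, p_e = ref.biallelic_freqs(j)
        if abs(p_e - p_w) < delta_min:
            rows.append({"locus": locus, "p_value": np.nan, "mode": "excluded",
                         "fst": np.nan, "p_E": p_e, "p_W": p_w})
            continue
        f = ref.freqs[j]
        e_allele = max(f, key=lambda a: f[a][1] - f[a][0])
        dose = (gm.geno[:, j, :] == e_allele).sum(axis=1).astype(np.int8)
        dose[gm.geno[:, j, 0] == MISSING] = MISSING
        res = permutation_test(dose, h, p_e, p_w, B=B, rng=rng, locus=locus)
        if pops_w is not None and pops_e is not None:
            res.fst = fst_between_panels(gm, j, pops_w, pops_e)
        classify_selection(res, alpha=alpha)
        results.append(res)
        rows.append({"locus": locus, "p_value": res.p_value, "mode": res.mode,
                     "fst": res.fst, "p_E": p_e, "p_W": p_w})
    return pd.DataFrame(rows), results
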