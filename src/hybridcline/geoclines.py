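"""Geographic allele-frequency clines along a transect or elevation axis.

A cline is the symmetric two-parameter sigmoid

    p(x) = (1 + tanh(2 (x - c) / w)) / 2,

whose steepest point is the center ``c`` and whose width ``w`` is the inverse
of the maximum slope (dp/dx at x = c equals 1/w), so the reported per-100-km
slope always satisfies |slope| * width = 100.  Fitting maximizes the binomial
log-likelihood of per-population allele counts with deterministic multi-start
bounded optimization.  Multi-allelic SSR loci are first reduced to a
two-allele system by assigning each allele to a species-specific compound
allele using the parental frequency differential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .ancestry import DELTA_MIN, ParentalReference
from .io import MISSING, GenotypeMatrix

#: likelihood clamp, axis bounds and width floor for transect-distance fits
P_CLAMP = 1e-6
CENTER_BOUNDS_KM = (0.0, 2000.0)
WIDTH_BOUNDS_KM = (50.0, 1e6)
#: axis bounds and width floor for elevational fits (meters)
CENTER_BOUNDS_M = (0.0, 4000.0)
WIDTH_BOUNDS_M = (100.0, 1e7)


@dataclass
class ClineInput:
    """Per-population axis positions, species-E allele counts and gene copies."""

    x: np.ndarray
    k: np.ndarray
    n: np.ndarray
    locus: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.x.size < 3:
            raise ValueError("need at least 3 populations")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("allele counts must satisfy 0 <= k <= n")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("axis positions must be finite")


@dataclass
class ClineFit:
    """Fitted sigmoid cline: center (steepest point), width (inverse of the
    maximum slope), signed per-100-unit slope, and log-likelihood."""

    locus: str
    center: float
    width: float
    slope: float
    log_likelihood: float
    orientation: int
    no_cline: bool = False


def cline_frequency(x, c: float, w: float, orientation: int = 1):
    """Expected allele frequency at axis position ``x``.

    Rises from 0 to 1 through the center when ``orientation`` is +1, falls
    when -1; the maximum derivative magnitude 1/w occurs at x = c.
    """
    if w <= 0:
        raise ValueError("width must be positive")
    p = 0.5 * (1.0 + np.tanh(2.0 * (np.asarray(x, dtype=float) - c) / w))
    return p if orientation >= 0 else 1.0 - p


def _negll(params, x, k, n, orientation):
    c, logw = params
    p = cline_frequency(x, c, np.exp(logw), orientation)
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    return -(k * np.log(p) + (n - k) * np.log(1.0 - p)).sum()


def fit_cline(data: ClineInput, center_bounds=CENTER_BOUNDS_KM,
              width_bounds=WIDTH_BOUNDS_KM, n_starts: int = 20) -> ClineFit:
    """Maximum-likelihood sigmoid cline fit.

    Runs a deterministic multi-start (grid of >= ``n_starts`` (c, w) pairs)
    bounded quasi-Newton optimization on (c, log w) for both orientations and
    keeps the best.  Degenerate data with the same observed frequency in
    every population are flagged ``no_cline``.
    """
    freq = np.divide(data.k, data.n, out=np.full_like(data.k, np.nan),
                     where=data.n > 0)
    obs = freq[np.isfinite(freq)]
    if obs.size and np.ptp(obs) < 1e-12:
        return ClineFit(locus=data.locus, center=float("nan"),
                        width=float(width_bounds[1]), slope=0.0,
                        log_likelihood=float("nan"), orientation=1,
                        no_cline=True)

    n_c = max(5, int(np.ceil(n_starts / 4)))
    c_starts = np.linspace(center_bounds[0], center_bounds[1], n_c)
    w_hi = min(width_bounds[1], 4.0 * (center_bounds[1] - center_bounds[0]))
    w_starts = np.geomspace(width_bounds[0], w_hi, 4)
    bounds = [center_bounds,
              (np.log(width_bounds[0]), np.log(width_bounds[1]))]

    best = None
    for orientation in (1, -1):
        for c0 in c_starts:
            for w0 in w_starts:
                res = minimize(_negll, x0=[c0, np.log(w0)],
                               args=(data.x, data.k, data.n, orientation),
                               method="L-BFGS-B", bounds=bounds)
                if best is None or res.fun < best[0] - 1e-12:
                    best = (res.fun, res.x, orientation)
    nll, (c, logw), orientation = best
    w = float(np.exp(logw))
    return ClineFit(locus=data.locus, center=float(c), width=w,
                    slope=orientation * 100.0 / w, log_likelihood=-nll,
                    orientation=orientation)


def elevational_cline(data: ClineInput, center_bounds=CENTER_BOUNDS_M,
                      width_bounds=WIDTH_BOUNDS_M, n_starts: int = 20) -> ClineFit:
    """Cline fit on an elevation axis (meters); slope is per 100 m."""
    return fit_cline(data, center_bounds=center_bounds,
                     width_bounds=width_bounds, n_starts=n_starts)


def compare_centers(datasets: list[ClineInput], center_bounds=CENTER_BOUNDS_KM,
                    width_bounds=WIDTH_BOUNDS_KM) -> dict:
    """AIC comparison of shared-center vs independent-center cline models.

    Model (a): one center shared by all loci, per-locus widths (profiled by
    one-dimensional optimization at each candidate center).  Model (b):
    per-locus (c, w) fits.  AIC = 2p - 2 logL.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one locus")
    fits = [fit_cline(d, center_bounds, width_bounds) for d in datasets]
    logl_indep = sum(f.log_likelihood for f in fits)
    orientations = [f.orientation for f in fits]

    logw_bounds = (np.log(width_bounds[0]), np.log(width_bounds[1]))

    def profile_negll(c):
        total = 0.0
        for d, orientation in zip(datasets, orientations):
            inner = minimize_scalar(
                lambda lw: _negll((c, lw), d.x, d.k, d.n, orientation),
                bounds=logw_bounds, method="bounded")
            total += inner.fun
        return total

    c_grid = np.linspace(center_bounds[0], center_bounds[1], 41)
    grid_vals = [profile_negll(c) for c in c_grid]
    i = int(np.argmin(grid_vals))
    lo = c_grid[max(i - 1, 0)]
    hi = c_grid[min(i + 1, len(c_grid) - 1)]
    refine = minimize_scalar(profile_negll, bounds=(lo, hi), method="bounded")
    shared_nll = min(refine.fun, grid_vals[i])
    shared_c = refine.x if refine.fun <= grid_vals[i] else c_grid[i]

    L = len(datasets)
    p_shared, p_indep = 1 + L, 2 * L
    if L == 1:  # models coincide: the shared center is the locus's own
        p_shared = p_indep
        shared_nll = -logl_indep
    aic_shared = 2 * p_shared + 2 * shared_nll
    aic_indep = 2 * p_indep - 2 * logl_indep
    return {
        "fits": fits,
        "shared_center": float(shared_c),
        "logL_shared": float(-shared_nll),
        "logL_independent": float(logl_indep),
        "aic_shared": float(aic_shared),
        "aic_independent": float(aic_indep),
        "delta_aic": float(aic_shared - aic_indep),
        "preferred": "shared" if aic_shared <= aic_indep else "independent",
    }


# ---------------------------------------------------------------------------
# Compound-allele reduction of multi-allelic loci
# ---------------------------------------------------------------------------

def compound_allele_reduction(gm: GenotypeMatrix, ref: ParentalReference,
                              delta_min: float = DELTA_MIN):
    """Reduce multi-allelic loci to a two-allele (W/E compound) system.

    Each allele is assigned to the species where its parental-panel frequency
    is higher (ties to W); codes become 0 = W-compound, 1 = E-compound.  Loci
    monomorphic across both panels are excluded with a warning.  Returns the
    reduced :class:`GenotypeMatrix` and the mapping table.
    """
    keep, mappings, map_rows = [], [], []
    for j in range(gm.n_loci):
        freqs = ref.freqs[j]
        if len(freqs) < 2:
            warnings.warn(f"locus {gm.loci[j]}: monomorphic across parental "
                          "panels; excluded from compound reduction")
            continue
        mapping = {}
        for a, (pw, pe) in freqs.items():
            compound = 1 if pe > pw else 0
            mapping[a] = compound
            map_rows.append({"locus": gm.loci[j], "allele": a, "p_W": pw,
                             "p_E": pe, "compound": "E" if compound else "W",
                             "ambiguous": abs(pe - pw) <= delta_min})
        keep.append(j)
        mappings.append(mapping)

    geno = np.full((gm.n_individuals, len(keep), 2), MISSING, dtype=np.int8)
    for out_j, (j, mapping) in enumerate(zip(keep, mappings)):
        col = gm.geno[:, j, :]
        for a, compound in mapping.items():
            geno[:, out_j, :][col == a] = compound
        # alleles never seen in the panels default to the W compound (tie rule)
        geno[:, out_j, :][(col != MISSING) & (geno[:, out_j, :] == MISSING)] = 0
    reduced = GenotypeMatrix(ids=list(gm.ids), pops=gm.pops.copy(),
                             loci=[gm.loci[j] for j in keep], geno=geno,
                             marker_class=["SNP"] * len(keep))
    return reduced, pd.DataFrame(map_rows)


def cline_input_from_genotypes(gm: GenotypeMatrix, meta: pd.DataFrame,
                               locus, axis: str = "distance_km") -> ClineInput:
    """Per-population counts of the E (allele code 1) allele for one locus.

    ``gm`` must be bi-allelic with codes {0, 1} (SNPs or compound-reduced
    SSRs); populations are matched to ``meta`` rows by label.
    """
    j = gm.loci.index(locus) if isinstance(locus, str) else locus
    x, k, n = [], [], []
    for row in meta.itertuples():
        rows = gm.pop_rows(row.population)
        if rows.size == 0:
            continue
        g = gm.geno[rows, j, :]
        g = g[g != MISSING]
        x.append(getattr(row, axis))
        k.append(int((g == 1).sum()))
        n.append(int(g.size))
    return ClineInput(x=np.asarray(x), k=np.asarray(k), n=np.asarray(n),
                      locus=gm.loci[j])


def fit_all_clines(gm: GenotypeMatrix, meta: pd.DataFrame,
                   axis: str = "distance_km", **kwargs) -> pd.DataFrame:
    """Fit a geographic cline to every locus; returns a Table-style frame."""
    rows = []
    for locus in gm.loci:
        data = cline_input_from_genotypes(gm, meta, locus, axis)
        fit = fit_cline(data, **kwargs) if axis == "distance_km" \
            else elevational_cline(data, **kwargs)
        rows.append({"locus": locus, "center": fit.center, "slope": fit.slope,
                     "width": fit.width, "logL": fit.log_likelihood,
                     "no_cline": fit.no_cline})
    return pd.DataFrame(rows)
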