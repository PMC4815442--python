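"""Hybrid index and interspecific heterozygosity from parental references.

Given allele frequencies in two parental reference panels (a "white"/W panel
and an "Engelmann"/E panel, generically species A and B), the hybrid index h
of an individual is the fraction of its genome derived from species E,
estimated by maximum likelihood: each non-missing allele copy a contributes
P(a | h) = h * p_E(a) + (1 - h) * p_W(a) and the product over copies is
maximized over a fine grid of h.  Interspecific heterozygosity is the
proportion of loci carrying one allele assigned to each species, using a hard
frequency-differential assignment of alleles to species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

#: default minimum parental frequency differential for assigning an allele
DELTA_MIN = 0.2

#: grid step of the maximum-likelihood search over h
H_GRID_STEP = 5e-4


@dataclass
class ParentalReference:
    """Per-locus allele frequencies in the two parental panels.

    ``freqs[l]`` maps allele code -> (p_W, p_E); ``n_w``/``n_e`` are panel
    sizes in gene copies per locus.
    """

    loci: list[str]
    freqs: list[dict[int, tuple[float, float]]]
    n_w: np.ndarray
    n_e: np.ndarray

    @classmethod
    def from_panels(cls, gm: GenotypeMatrix, pops_w, pops_e) -> "ParentalReference":
        """Build a reference from designated parental populations."""
        rows_w = np.where(np.isin(gm.pops, np.atleast_1d(pops_w)))[0]
        rows_e = np.where(np.isin(gm.pops, np.atleast_1d(pops_e)))[0]
        if rows_w.size == 0 or rows_e.size == 0:
            raise ValueError("empty parental panel")
        freqs, n_w, n_e = [], [], []
        for j in range(gm.n_loci):
            cw = gm.allele_counts(j, rows_w)
            ce = gm.allele_counts(j, rows_e)
            tw, te = sum(cw.values()), sum(ce.values())
            alleles = sorted(set(cw) | set(ce))
            freqs.append({a: (cw.get(a, 0) / tw if tw else 0.0,
                              ce.get(a, 0) / te if te else 0.0)
                          for a in alleles})
            n_w.append(tw)
            n_e.append(te)
        return cls(loci=list(gm.loci), freqs=freqs,
                   n_w=np.asarray(n_w), n_e=np.asarray(n_e))

    def swapped(self) -> "ParentalReference":
        """Reference with the two species' panels exchanged."""
        return ParentalReference(
            loci=list(self.loci),
            freqs=[{a: (pe, pw) for a, (pw, pe) in f.items()} for f in self.freqs],
            n_w=self.n_e.copy(), n_e=self.n_w.copy())

    def biallelic_freqs(self, locus: int) -> tuple[float, float]:
        """(p_W, p_E) of the E-representative allele at a bi-allelic locus.

        The E allele is the allele with the larger E-panel frequency
        (p_E >= p_W orientation used by genomic clines).
        """
        f = self.freqs[locus]
        best = max(f, key=lambda a: f[a][1] - f[a][0])
        return f[best]


@dataclass
class AncestryRecord:
    """Per-individual hybrid index and interspecific heterozygosity."""

    individual: str
    h: float
    log_likelihood: float
    h_low: float
    h_high: float
    interspecific_het: float
    n_loci: int


def allele_ancestry(p_e: float, p_w: float, delta_min: float = DELTA_MIN) -> str:
    """Assign an allele to a species by parental frequency differential.

    Returns ``"E"`` if p_E - p_W > delta_min, ``"W"`` if p_W - p_E >
    delta_min, else ``"ambiguous"``.
    """
    if p_e - p_w > delta_min:
        return "E"
    if p_w - p_e > delta_min:
        return "W"
    return "ambiguous"


def _collect_copy_freqs(genotype_row, ref: ParentalReference):
    """Per-copy (p_W, p_E) for all usable allele copies; skips loci with
    alleles absent from both panels (warned) and missing genotypes."""
    pw, pe = [], []
    n_used = 0
    g = np.asarray(genotype_row)
    for j in range(g.shape[0]):
        a, b = int(g[j, 0]), int(g[j, 1])
        if a == MISSING:
            continue
        fj = ref.freqs[j]
        if a not in fj or b not in fj:
            warnings.warn(f"locus {ref.loci[j]}: allele absent from both "
                          "parental panels; locus skipped")
            continue
        pwa, pea = fj[a]
        pwb, peb = fj[b]
        if (pwa == 0 and pea == 0) or (pwb == 0 and peb == 0):
            warnings.warn(f"locus {ref.loci[j]}: allele with zero frequency "
                          "in both panels; locus skipped")
            continue
        pw.extend([pwa, pwb])
        pe.extend([pea, peb])
        n_used += 1
    return np.asarray(pw), np.asarray(pe), n_used


def _h_grid(step: float = H_GRID_STEP) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def hybrid_index_ml(genotype_row, ref: ParentalReference,
                    grid_step: float = H_GRID_STEP,
                    support_drop: float = 2.0):
    """Maximum-likelihood hybrid index of one individual.

    Maximizes sum over allele copies of log[h p_E(a) + (1-h) p_W(a)] on an
    h grid of the given step.  Returns ``(h_hat, logL, (h_low, h_high),
    n_loci_used)`` where the interval is the ``support_drop``-unit
    log-likelihood support region around the maximum.
    """
    pw, pe, n_used = _collect_copy_freqs(genotype_row, ref)
    if n_used == 0:
        raise ValueError("no locus usable against the parental reference")
    h = _h_grid(grid_step)
    lik = h[:, None] * pe[None, :] + (1.0 - h)[:, None] * pw[None, :]
    with np.errstate(divide="ignore"):
        logl = np.log(lik).sum(axis=1)
    best = int(np.argmax(logl))
    inside = np.where(logl >= logl[best] - support_drop)[0]
    return float(h[best]), float(logl[best]), \
        (float(h[inside[0]]), float(h[inside[-1]])), n_used


def interspecific_heterozygosity(genotype_row, ref: ParentalReference,
                                 delta_min: float = DELTA_MIN) -> float:
    """Proportion of loci with one allele from each ancestral species.

    Only loci where both allele copies have unambiguous ancestry count
    toward the denominator; returns NaN when no locus is assessable.
    """
    g = np.asarray(genotype_row)
    het = assessable = 0
    for j in range(g.shape[0]):
        a, b = int(g[j, 0]), int(g[j, 1])
        if a == MISSING:
            continue
        fj = ref.freqs[j]
        if a not in fj or b not in fj:
            continue
        anc_a = allele_ancestry(fj[a][1], fj[a][0], delta_min)
        anc_b = allele_ancestry(fj[b][1], fj[b][0], delta_min)
        if "ambiguous" in (anc_a, anc_b):
            continue
        assessable += 1
        if anc_a != anc_b:
            het += 1
    if assessable == 0:
        return float("nan")
    return het / assessable


def biallelic_ml_hybrid_index(dosage, p_w, p_e,
                              grid_step: float = H_GRID_STEP) -> np.ndarray:
    """Vectorized grid-ML hybrid index for complete bi-allelic dosage data.

    ``dosage`` is an (n, L) matrix counting copies of the species-E allele;
    ``p_w``/``p_e`` are that allele's panel frequencies per locus.  Equivalent
    to :func:`hybrid_index_ml` locus by locus but evaluated as two matrix
    products, which makes whole-simulation scoring practical.
    """
    dosage = np.asarray(dosage, dtype=float)
    p_w = np.asarray(p_w, dtype=float)
    p_e = np.asarray(p_e, dtype=float)
    h = _h_grid(grid_step)
    q1 = h[:, None] * p_e[None, :] + (1.0 - h)[:, None] * p_w[None, :]
    l1 = np.log(np.maximum(q1, 1e-300))
    l0 = np.log(np.maximum(1.0 - q1, 1e-300))
    logl = dosage @ l1.T + (2.0 - dosage) @ l0.T
    return h[np.argmax(logl, axis=1)]


def biallelic_interspecific_het(dosage, p_w, p_e,
                                delta_min: float = DELTA_MIN):
    """Vectorized interspecific heterozygosity for bi-allelic dosage data.

    Only loci whose parental frequency differential exceeds ``delta_min``
    are assessable; returns (het per individual, number of assessable loci).
    Individuals get NaN when no locus is assessable.
    """
    dosage = np.asarray(dosage)
    keep = np.abs(np.asarray(p_e) - np.asarray(p_w)) > delta_min
    n_keep = int(keep.sum())
    if n_keep == 0:
        return np.full(dosage.shape[0], np.nan), 0
    return (dosage[:, keep] == 1).mean(axis=1), n_keep


def estimate_ancestry(gm: GenotypeMatrix, ref: ParentalReference,
                      grid_step: float = H_GRID_STEP,
                      delta_min: float = DELTA_MIN) -> pd.DataFrame:
    """Hybrid index and interspecific heterozygosity for every individual.

    Returns a DataFrame with columns id, pop, h, h_low, h_high, logL,
    int_het, n_loci.
    """
    rows = []
    for i in range(gm.n_individuals):
        g = gm.geno[i]
        h, logl, (lo, hi), n_used = hybrid_index_ml(g, ref, grid_step)
        het = interspecific_heterozygosity(g, ref, delta_min)
        rows.append({"id": gm.ids[i], "pop": gm.pops[i], "h": h,
                     "h_low": lo, "h_high": hi, "logL": logl,
                     "int_het": het, "n_loci": n_used})
    return pd.DataFrame(rows)


def purge_reference_panels(gm: GenotypeMatrix, pops_w, pops_e,
                           max_admixture: float = 0.1,
                           grid_step: float = H_GRID_STEP):
    """Optionally purge admixed individuals from the designated panels.

    Each panel member is scored against the reference built from the
    remaining panel individuals; members with hybrid index inside
    (max_admixture, 1 - max_admixture) are dropped.  Returns the row indices
    retained for each panel.
    """
    rows_w = np.where(np.isin(gm.pops, np.atleast_1d(pops_w)))[0]
    rows_e = np.where(np.isin(gm.pops, np.atleast_1d(pops_e)))[0]
    ref = ParentalReference.from_panels(gm, pops_w, pops_e)
    keep_w, keep_e = [], []
    for i in rows_w:
        h, *_ = hybrid_index_ml(gm.geno[i], ref, grid_step)
        if h <= max_admixture:
            keep_w.append(i)
    for i in rows_e:
        h, *_ = hybrid_index_ml(gm.geno[i], ref, grid_step)
        if h >= 1.0 - max_admixture:
            keep_e.append(i)
    return np.asarray(keep_w), np.asarray(keep_e)


def triangle_summary(records: pd.DataFrame, group_col: str = "pop") -> pd.DataFrame:
    """Group means/variances of (h, interspecific het) for triangle plots."""
    if len(records) == 0:
        raise ValueError("no ancestry records")
    out = records.groupby(group_col).agg(
        n=("h", "size"),
        mean_h=("h", "mean"), var_h=("h", "var"),
        mean_int_het=("int_het", "mean"), var_int_het=("int_het", "var"),
    ).reset_index()
    return out


def classify_modality(h_values, n_bins: int = 20,
                      prominence: float = 0.05) -> str:
    """Classify a hybrid-index distribution as uni-, bi- or trimodal.

    Histogram with ``n_bins`` equal bins on [0, 1]; modes are local maxima
    whose count exceeds ``prominence`` * n.  Trimodal requires modes in
    [0, 0.1], (0.1, 0.9) and [0.9, 1]; bimodal only in the two edge regions.
    """
    h = np.asarray(h_values, dtype=float)
    if h.size < 30:
        raise ValueError("need at least 30 values for a stable modality call")
    counts, edges = np.histogram(h, bins=n_bins, range=(0.0, 1.0))
    padded = np.concatenate([[-1], counts, [-1]])
    is_peak = (counts >= padded[:-2]) & (counts > padded[2:]) & \
        (counts >= prominence * h.size)
    centers = 0.5 * (edges[:-1] + edges[1:])
    low = np.any(is_peak & (centers <= 0.1))
    high = np.any(is_peak & (centers >= 0.9))
    mid = np.any(is_peak & (centers > 0.1) & (centers < 0.9))
    if low and high and mid:
        return "trimodal"
    if low and high:
        return "bimodal"
    return "unimodal"
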