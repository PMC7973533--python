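"""GRM-corrected association scan and carrier-removal impact analysis.

``mlma_scan`` fits the null mixed model y = mu + g + e with cov(g) =
sigma_g^2 * GRM once by restricted maximum likelihood (exact one-dimensional
profile over the variance ratio on the GRM eigenbasis), then tests each SNP
by generalized least squares at the fitted covariance, treating binary
carrier status as a quantitative 0/1 trait. Chromosome-wise q-values use the
Storey smoother estimate of pi0, falling back to Benjamini-Hochberg when the
estimate is unstable or a chromosome has too few tests.

``carrier_removal_impact`` compares the full genotyped cohort with the
cohort after removing carriers and affected animals of one disease: per-SNP
minor-allele-frequency change with the A1 assignment frozen on the full
cohort, plus multi-locus heterozygosity, observed/expected heterozygosity
and ROH summaries for both cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats

from breeddiv.genotypes import GenotypeMatrix, allele_frequencies, het_stats, mlh
from breeddiv.roh import ROHParams, detect_roh, froh, roh_summary


# ---------------------------------------------------------------------------
# Mixed linear model association
# ---------------------------------------------------------------------------

def _reml_variance_ratio(
    yr: np.ndarray, ones_r: np.ndarray, d: np.ndarray, max_log_lambda: float = 12.0
) -> float:
    """Profile-REML estimate of lambda = sigma_g^2/sigma_e^2 on the eigenbasis.

    ``yr``/``ones_r`` are the rotated phenotype and intercept; ``d`` the GRM
    eigenvalues. With a single random effect the restricted likelihood for
    V = lambda*D + I is one-dimensional in lambda (the GLS intercept and the
    scale are profiled out in closed form) and is solved by bounded scalar
    minimization.
    """
    n = len(yr)

    def neg_restricted_ll(log_lam: float) -> float:
        lam = math.exp(log_lam)
        w = 1.0 / (lam * d + 1.0)
        xwx = float(np.sum(w * ones_r * ones_r))
        beta = float(np.sum(w * ones_r * yr)) / xwx
        resid = yr - beta * ones_r
        rss = float(np.sum(w * resid * resid))
        sigma2 = rss / (n - 1)
        return float(-np.sum(np.log(w)) + (n - 1) * math.log(sigma2) + math.log(xwx))

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(-max_log_lambda, max_log_lambda),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML failed to converge: {res.message}")
    # boundary at the lower end means sigma_g ~ 0
    lam = math.exp(res.x)
    return 0.0 if res.x <= -max_log_lambda + 1e-6 else lam


def mlma_scan(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    status: pd.Series,
    grm_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Per-SNP mixed-linear-model association of 0/1 status with dosage.

    Variance components are estimated once on the null model; each SNP is
    then tested by GLS given the fitted covariance. Returns a frame indexed
    like the marker map with columns beta, se, p (monomorphic SNPs get p=1).
    """
    y = status.loc[G.ids].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("status must have at least two classes")
    A = grm_matrix.loc[G.ids, G.ids].to_numpy(dtype=float)
    A = (A + A.T) / 2.0
    evals, U = np.linalg.eigh(A)
    evals = np.clip(evals, 0.0, None)

    n = len(y)
    yr = U.T @ y
    ones_r = U.T @ np.ones(n)
    lam = _reml_variance_ratio(yr, ones_r, evals)

    v = lam * evals + 1.0  # V / sigma_e^2 on the eigenbasis
    w = 1.0 / v

    calls = G.calls.astype(np.float64)
    miss = G.calls < 0
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(~miss, calls, 0).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
        calls = np.where(miss, col_mean[None, :], calls)
    Xr = U.T @ calls  # (n, m) rotated dosages

    # GLS regression of y on (intercept, dosage), vectorized over SNPs; the
    # intercept column is the rotated ones vector, weights 1/v per eigenmode
    a11 = float(np.sum(w * ones_r * ones_r))
    b1 = float(np.sum(w * ones_r * yr))
    a12 = (w * ones_r) @ Xr
    a22 = w @ (Xr * Xr)
    b2 = (w * yr) @ Xr
    det = a11 * a22 - a12 * a12
    good = det > 1e-10
    safe_det = np.where(good, det, 1.0)
    beta = (a11 * b2 - a12 * b1) / safe_det
    mu = (a22 * b1 - a12 * b2) / safe_det
    syy = float(np.sum(w * yr * yr))
    rss = syy - (mu * b1 + beta * b2)
    df = n - 2
    sigma2 = np.maximum(rss, 0.0) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 * a11 / safe_det)
        tstat = np.where(good, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    mono = ~good
    p = np.where(mono, 1.0, p)
    out = markers[["chrom", "id", "bp"]].copy()
    out["beta"] = np.where(mono, 0.0, beta)
    out["se"] = se
    out["p"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["lambda_reml"] = lam
    return out


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def _storey_pi0(p: np.ndarray) -> float | None:
    """Smoother estimate of the null proportion pi0; None when unstable."""
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0s = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    try:
        spline = interpolate.UnivariateSpline(lambdas, pi0s, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        return None
    if pi0 <= 0.0:
        return None
    return min(pi0, 1.0)  # the smoother routinely overshoots slightly; clip


def _qvals_one_group(p: np.ndarray, min_group: int = 20) -> tuple[np.ndarray, bool]:
    m = len(p)
    pi0 = None if m < min_group else _storey_pi0(p)
    fallback = pi0 is None
    if fallback:
        pi0 = 1.0  # Benjamini-Hochberg
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, fallback


def qvalues(p: pd.Series, groups: pd.Series | None = None) -> pd.Series:
    """Storey q-values, computed within each group (typically chromosome).

    Groups with fewer than 20 p-values, or with an unstable pi0 estimate,
    fall back to Benjamini-Hochberg (pi0 = 1) with a warning.
    """
    pv = p.to_numpy(dtype=float)
    if np.any((pv <= 0) | (pv > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if groups is None:
        q, fb = _qvals_one_group(pv)
        if fb:
            warnings.warn("pi0 estimate unstable; using Benjamini-Hochberg")
        return pd.Series(q, index=p.index, name="q")
    out = np.empty(len(pv))
    fell_back = []
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        out[mask], fb = _qvals_one_group(pv[mask])
        if fb:
            fell_back.append(g)
    if fell_back:
        warnings.warn(
            f"pi0 unstable or too few tests in group(s) {fell_back[:5]}; "
            "used Benjamini-Hochberg there"
        )
    return pd.Series(out, index=p.index, name="q")


# ---------------------------------------------------------------------------
# LD profile around an anchor SNP
# ---------------------------------------------------------------------------

def ld_r2_profile(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    anchor: str,
    window_bp: float = 5e6,
    strong: float = 0.8,
    moderate: float = 0.5,
) -> pd.DataFrame:
    """Composite r^2 between the anchor SNP and every SNP within a window.

    Classes: strong (r^2 >= 0.8), moderate (0.5 <= r^2 < 0.8), weak.
    """
    idx = markers.index[markers["id"] == anchor]
    if len(idx) == 0:
        raise KeyError(f"anchor SNP {anchor!r} not in map")
    j = int(idx[0])
    a = G.calls[:, j].astype(float)
    a[G.calls[:, j] < 0] = np.nan
    if np.nanstd(a) == 0:
        raise ValueError(f"anchor SNP {anchor!r} is monomorphic")
    chrom = int(markers["chrom"].iloc[j])
    bp = int(markers["bp"].iloc[j])
    sel = markers.index[
        (markers["chrom"] == chrom) & (np.abs(markers["bp"] - bp) <= window_bp)
    ]
    rows = []
    for k in sel:
        b = G.calls[:, int(k)].astype(float)
        b[G.calls[:, int(k)] < 0] = np.nan
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3 or b[ok].std() == 0:
            r2 = np.nan
        else:
            r = np.corrcoef(a[ok], b[ok])[0, 1]
            r2 = float(r * r)
        cls = (
            "strong"
            if r2 >= strong
            else "moderate" if r2 >= moderate else "weak"
        ) if not np.isnan(r2) else "weak"
        rows.append(
            {
                "id": markers["id"].iloc[int(k)],
                "chrom": chrom,
                "bp": int(markers["bp"].iloc[int(k)]),
                "r2": r2,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Carrier-removal impact
# ---------------------------------------------------------------------------

@dataclass
class ImpactReport:
    """Full-vs-cleared cohort comparison after carrier/affected removal."""

    snp_table: pd.DataFrame  # id, chrom, bp, maf_full, maf_cleared, delta_maf
    n_full: int
    n_cleared: int
    removed_ids: list[str]
    mlh_full: float
    mlh_cleared: float
    ho_full: float
    ho_cleared: float
    he_full: float
    he_cleared: float
    froh_full: float
    froh_cleared: float
    roh_summary_full: pd.DataFrame
    roh_summary_cleared: pd.DataFrame
    flagged: dict[float, pd.DataFrame] = field(default_factory=dict)
    causal_chrom: int | None = None
    causal_chrom_table: pd.DataFrame | None = None


def carrier_removal_impact(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    status: pd.Series,
    maf_flags: tuple[float, ...] = (0.05, 0.10),
    roh_params: ROHParams | None = None,
    roh_classes_kb: tuple[float, ...] = (1000.0, 2000.0, 4000.0, 8000.0),
    causal_chrom: int | None = None,
) -> ImpactReport:
    """Quantify diversity and allele-frequency impact of removing carriers.

    ``status`` maps individual id to {affected, carrier, normal, untested};
    affected and carrier animals are removed, normal and untested retained.
    The minor-allele orientation (A1) is frozen from the full cohort, so
    delta_MAF = freq_cleared - freq_full has a stable sign.
    """
    status = status.reindex(G.ids).fillna("untested")
    remove = status.isin(["affected", "carrier"]).to_numpy()
    keep = np.flatnonzero(~remove)
    if keep.size == 0:
        raise ValueError("removal empties the cohort")
    cleared = G.subset(rows=keep)

    freq_full = allele_frequencies(G)["freq_a1"].to_numpy()
    freq_clr = allele_frequencies(cleared)["freq_a1"].to_numpy()
    snp_table = markers[["id", "chrom", "bp"]].copy()
    snp_table["maf_full"] = freq_full
    snp_table["maf_cleared"] = freq_clr
    snp_table["delta_maf"] = freq_clr - freq_full

    flagged = {
        t: snp_table[np.abs(snp_table["delta_maf"]) >= t].reset_index(drop=True)
        for t in maf_flags
    }

    hs_full = het_stats(G)
    hs_clr = het_stats(cleared)
    segs_full = detect_roh(G, markers, roh_params)
    segs_clr = detect_roh(cleared, markers, roh_params)

    report = ImpactReport(
        snp_table=snp_table,
        n_full=G.n_individuals,
        n_cleared=cleared.n_individuals,
        removed_ids=[G.ids[i] for i in np.flatnonzero(remove)],
        mlh_full=float(mlh(G).mean()),
        mlh_cleared=float(mlh(cleared).mean()),
        ho_full=float(hs_full["Ho"].mean()),
        ho_cleared=float(hs_clr["Ho"].mean()),
        he_full=float(hs_full["He"].mean()),
        he_cleared=float(hs_clr["He"].mean()),
        froh_full=float(froh(segs_full, markers, G.n_individuals)),
        froh_cleared=float(froh(segs_clr, markers, cleared.n_individuals)),
        roh_summary_full=roh_summary(G, markers, roh_classes_kb, roh_params),
        roh_summary_cleared=roh_summary(cleared, markers, roh_classes_kb, roh_params),
        flagged=flagged,
        causal_chrom=causal_chrom,
    )
    if causal_chrom is not None:
        report.causal_chrom_table = snp_table[
            snp_table["chrom"] == causal_chrom
        ].reset_index(drop=True)
    return report


# ---------------------------------------------------------------------------
# Mutual k-nearest-neighbor network
# ---------------------------------------------------------------------------

def mknn_network(
    D: pd.DataFrame, k: int = 10, statuses: pd.Series | None = None
) -> nx.Graph:
    """Mutual k-nearest-neighbor graph from a distance matrix.

    Edge (a, b) exists iff each is among the other's k nearest neighbors
    (distance ties broken by id order). Node attribute ``status`` carries the
    disease status when provided. Graph attributes report connected-component
    count and per-status mean clustering coefficient.
    """
    n = len(D)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of individuals {n}")
    ids = list(D.index)
    dist = D.to_numpy(dtype=float)
    neighbor_sets: list[set[int]] = []
    for i in range(n):
        order = sorted((dist[i, j], ids[j], j) for j in range(n) if j != i)
        neighbor_sets.append({j for _, _, j in order[:k]})
    graph = nx.Graph()
    for i, iid in enumerate(ids):
        graph.add_node(iid)
        if statuses is not None:
            graph.nodes[iid]["status"] = statuses.get(iid, "untested")
    for i in range(n):
        for j in neighbor_sets[i]:
            if j > i and i in neighbor_sets[j]:
                graph.add_edge(ids[i], ids[j], distance=float(dist[i, j]))
    graph.graph["n_components"] = nx.number_connected_components(graph)
    if statuses is not None:
        clust = nx.clustering(graph)
        by_status: dict[str, list[float]] = {}
        for node, c in clust.items():
            by_status.setdefault(graph.nodes[node].get("status", "untested"), []).append(c)
        graph.graph["clustering_by_status"] = {
            s: float(np.mean(v)) for s, v in by_status.items()
        }
    return graph
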