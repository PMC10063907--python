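"""Functional connectivity from stimulation blocks.

Scan-level networks: concatenate the stimulation-block samples, prewhiten
each channel with an AR model selected by BIC (filter state reset at block
boundaries), estimate every pairwise correlation with an iteratively
reweighted robust estimator, and attach r -> t -> p -> Benjamini-Hochberg q
significance. Group-level networks: Fisher-z correlations modeled per edge
with a linear mixed-effects model (group, week, group x week fixed effects,
random subject intercept); cell estimates are back-transformed marginal
means. The differential symmetry index (DSI) quantifies the overlap of two
binarized networks beyond what their densities alone would produce.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.stattools import acovf

from .scan import HB, Scan

#: robust-correlation tuning: bisquare cutoff on the bivariate Mahalanobis
#: distance (~99.9th percentile of a chi(2) variate)
BISQUARE_C = 5.0


@dataclass
class ConnectivityNetwork:
    """Symmetric channel x channel correlation network with significance."""

    channels: list[str]
    r: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_effective: int
    hb_type: str
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def upper_triangle(self, matrix: str = "r") -> np.ndarray:
        m = getattr(self, matrix)
        iu = np.triu_indices(self.n_channels, k=1)
        return m[iu]

    def edges(self):
        """Iterate (i, j, r, q) over unique off-diagonal pairs."""
        nc = self.n_channels
        for i in range(nc):
            for j in range(i + 1, nc):
                yield i, j, self.r[i, j], self.q[i, j]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ch_i": self.channels[i], "ch_j": self.channels[j],
             "r": self.r[i, j], "t": self.t[i, j],
             "p": self.p[i, j], "q": self.q[i, j]}
            for i in range(self.n_channels) for j in range(i + 1, self.n_channels)
        ]
        return pd.DataFrame(rows)


@dataclass
class PrewhitenResult:
    innovations: np.ndarray
    ar_order: int
    ar_coefficients: np.ndarray


# ---------------------------------------------------------------- segments

def extract_stimulation_segments(scan: Scan, events: np.ndarray | None = None,
                                 stim_duration: float | None = None) -> list[tuple[int, int]]:
    """Sample-index windows [start, stop) of the stimulation blocks.

    ``stim_duration`` overrides the per-event durations when given. Blocks
    must not overlap and must lie within the recording.
    """
    events = scan.events if events is None else np.asarray(events, float).reshape(-1, 2)
    fs = scan.sampling_rate
    n = scan.n_samples
    segs = []
    for onset, dur in events:
        if stim_duration is not None:
            dur = stim_duration
        i0 = round(onset * fs)
        i1 = i0 + round(dur * fs)
        if i0 < 0 or i1 > n:
            raise ValueError(f"stimulation block [{onset}, {onset + dur}] s out of bounds")
        segs.append((i0, i1))
    segs.sort()
    for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
        if b0 < a1:
            raise ValueError("overlapping stimulation blocks")
    return segs


# ---------------------------------------------------------------- prewhitening

def _levinson(acov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Levinson-Durbin recursion: AR coefficients and innovation variance
    for every order 0..max given autocovariances 0..max."""
    p = len(acov) - 1
    phi = np.zeros((p + 1, p + 1))
    sigma = np.zeros(p + 1)
    sigma[0] = acov[0]
    for k in range(1, p + 1):
        num = acov[k] - phi[1:k, k - 1] @ acov[1:k][::-1]
        rk = num / sigma[k - 1]
        phi[k, k] = rk
        phi[1:k, k] = phi[1:k, k - 1] - rk * phi[1:k, k - 1][::-1]
        sigma[k] = sigma[k - 1] * (1.0 - rk * rk)
    return phi, sigma


def ar_prewhiten(series: np.ndarray, max_order: int = 27,
                 breaks: np.ndarray | None = None,
                 order: int | None = None) -> PrewhitenResult:
    """Fit an AR(p) model (p BIC-selected over 0..max_order) and return the
    innovation series.

    ``breaks`` marks indices where the series is a concatenation of
    independent segments (stimulation blocks); the AR filter state is reset
    there and the first p samples of each segment are dropped, so
    cross-segment dynamics never leak into the innovations. Without breaks,
    innovations have length n - p.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input series")
    n = len(x)
    if n <= 2 * max_order:
        raise ValueError("series too short for the requested max_order")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance (constant) series cannot be prewhitened")

    xm = x - x.mean()
    ac = acovf(xm, nlag=max_order, fft=True)
    phi, sigma = _levinson(ac)
    if order is None:
        sigma = np.maximum(sigma, 1e-300)
        bic = n * np.log(sigma) + np.arange(max_order + 1) * math.log(n)
        order = int(np.argmin(bic))
    coefs = phi[1:order + 1, order].copy()

    bounds = [0, n] if breaks is None else [0, *sorted(int(b) for b in breaks), n]
    pieces = []
    b = np.r_[1.0, -coefs]
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        seg = xm[s0:s1]
        if order == 0:
            pieces.append(seg)
        elif len(seg) > order:
            innov = np.convolve(seg, b, mode="full")[order:len(seg)]
            pieces.append(innov)
    return PrewhitenResult(innovations=np.concatenate(pieces) if pieces else xm[:0],
                           ar_order=order, ar_coefficients=coefs)


# ---------------------------------------------------------------- robust correlation

def _robust_corr_pairs(x: np.ndarray, y: np.ndarray, c: float = BISQUARE_C,
                       tol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Vectorized IRLS correlation for row-paired series (m_pairs, n)."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    m, n = x.shape
    if y.shape != x.shape:
        raise ValueError("paired inputs must share shape")
    if n < 10:
        raise ValueError("at least 10 samples required")
    w = np.ones_like(x)
    r = np.zeros(m)
    eps = 1e-12
    for _ in range(max_iter):
        sw = w.sum(axis=1)
        mx = (w * x).sum(axis=1) / sw
        my = (w * y).sum(axis=1) / sw
        dx = x - mx[:, None]
        dy = y - my[:, None]
        vx = (w * dx * dx).sum(axis=1) / sw
        vy = (w * dy * dy).sum(axis=1) / sw
        if np.any(vx <= 0) or np.any(vy <= 0):
            raise ValueError("zero variance in robust correlation input")
        cov = (w * dx * dy).sum(axis=1) / sw
        r = np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0)
        zx = dx / np.sqrt(vx)[:, None]
        zy = dy / np.sqrt(vy)[:, None]
        d2 = (zx * zx - 2 * r[:, None] * zx * zy + zy * zy)
        d2 = np.maximum(d2, 0.0) / np.maximum(1 - r * r, eps)[:, None]
        d = np.sqrt(d2)
        w_new = np.where(d < c, (1 - (d / c) ** 2) ** 2, 0.0)
        # pathological all-zero weight rows fall back to uniform weights
        dead = w_new.sum(axis=1) < n * 0.1
        if dead.any():
            w_new[dead] = 1.0
        delta = np.abs(w_new - w).max()
        w = w_new
        if delta < tol:
            break
    return r


def robust_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Tukey-bisquare iteratively reweighted correlation of two series.

    Downweights samples by their bivariate Mahalanobis distance under the
    current correlation estimate, so gross outliers do not drive r.
    """
    return float(_robust_corr_pairs(np.asarray(x)[None, :], np.asarray(y)[None, :])[0])


def robust_correlation_matrix(data: np.ndarray) -> np.ndarray:
    """Symmetric robust correlation matrix of (n_samples, n_channels) data."""
    n, nch = data.shape
    iu = np.triu_indices(nch, k=1)
    x = data.T[iu[0]]
    y = data.T[iu[1]]
    r_flat = _robust_corr_pairs(x, y)
    r = np.eye(nch)
    r[iu] = r_flat
    r[(iu[1], iu[0])] = r_flat
    return r


# ---------------------------------------------------------------- significance

def attach_significance(r_matrix: np.ndarray, n_effective: int):
    """t, p and Benjamini-Hochberg q matrices for a correlation network.

    t = r sqrt(n-2) / sqrt(1-r^2); two-sided p from Student's t with n-2
    degrees of freedom; q corrected over the unique off-diagonal pairs.
    |r| = 1 maps to t = +/-inf, p = 0.
    """
    if n_effective <= 2:
        raise ValueError("n_effective must exceed 2")
    r = np.asarray(r_matrix, float)
    nc = r.shape[0]
    df = n_effective - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * math.sqrt(df) / np.sqrt(1.0 - r * r)
    t[np.abs(r) >= 1.0] = np.sign(r[np.abs(r) >= 1.0]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    iu = np.triu_indices(nc, k=1)
    q = np.zeros_like(p)
    if len(iu[0]):
        _, q_flat, _, _ = multipletests(p[iu], method="fdr_bh")
        q[iu] = q_flat
        q[(iu[1], iu[0])] = q_flat
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(t, np.inf)
    return t, p, q


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (thin wrapper, exposed for oracle tests)."""
    _, q, _, _ = multipletests(np.asarray(p_values, float), method="fdr_bh")
    return q


# ---------------------------------------------------------------- scan level

def scan_connectivity(scan: Scan, hb_type: str = "HbT",
                      max_order: int | None = None,
                      events: np.ndarray | None = None) -> ConnectivityNetwork:
    """Scan-level network from the concatenated stimulation blocks.

    Each channel is prewhitened with its own BIC-selected AR model (state
    reset at block boundaries); to keep innovation series aligned across
    channels, every channel drops max(p) initial samples per block. The
    robust pairwise correlation of the aligned innovations fills the network.
    """
    if scan.kind != HB:
        raise ValueError("connectivity expects a hemoglobin scan")
    if scan.n_channels < 2:
        raise ValueError("at least two channels required")
    data = scan.hb(hb_type)
    segs = extract_stimulation_segments(scan, events)
    if not segs:
        raise ValueError("no stimulation blocks to correlate")
    if max_order is None:
        max_order = math.ceil(2 * scan.sampling_rate)

    blocks = [data[i0:i1] for i0, i1 in segs]
    lengths = [b.shape[0] for b in blocks]
    concat = np.concatenate(blocks, axis=0)
    breaks = np.cumsum(lengths)[:-1]

    nch = scan.n_channels
    results = [ar_prewhiten(concat[:, c], max_order=max_order, breaks=breaks)
               for c in range(nch)]
    p_max = max(res.ar_order for res in results)
    # align channels: every channel drops p_max initial samples per block
    bounds = [0, *breaks.tolist(), concat.shape[0]]
    innov_cols = []
    for res in results:
        pieces, pos = [], 0
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            seg_len = (s1 - s0) - res.ar_order
            piece = res.innovations[pos:pos + seg_len]
            pieces.append(piece[p_max - res.ar_order:])
            pos += seg_len
        innov_cols.append(np.concatenate(pieces))
    innov = np.column_stack(innov_cols)

    r = robust_correlation_matrix(innov)
    n_eff = innov.shape[0]
    t, p, q = attach_significance(r, n_eff)
    return ConnectivityNetwork(channels=scan.probe.channel_names, r=r, t=t, p=p,
                               q=q, n_effective=n_eff, hb_type=hb_type,
                               provenance={k: scan.meta.get(k) for k in
                                           ("subject", "group", "week", "stimulus")})


# ---------------------------------------------------------------- group level

def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def group_connectivity(networks: list[ConnectivityNetwork],
                       method: str = "lme") -> dict[tuple[str, int], ConnectivityNetwork]:
    """Group-level networks per (group, week) cell from scan-level networks.

    ``method="lme"``: per edge, Fisher-z r is modeled with fixed effects
    group, week and their interaction plus a random subject intercept; the
    cell estimate is the back-transformed marginal mean and the edge p-value
    a Wald test of that mean against zero. ``method="mean"``: simple cell
    means with one-sample t-tests. Cells with fewer than 2 observations are
    excluded (flagged NaN).
    """
    if not networks:
        raise ValueError("no networks supplied")
    channels = networks[0].channels
    nc = len(channels)
    iu = np.triu_indices(nc, k=1)
    Z = np.stack([_fisher_z(net.r[iu]) for net in networks])
    meta = pd.DataFrame([net.provenance for net in networks])
    hb_type = networks[0].hb_type
    cells = sorted({(g, w) for g, w in zip(meta["group"], meta["week"])})
    cell_masks = {cell: ((meta["group"] == cell[0]) & (meta["week"] == cell[1])).to_numpy()
                  for cell in cells}

    n_edges = len(iu[0])
    est = {cell: np.full(n_edges, np.nan) for cell in cells}
    pval = {cell: np.full(n_edges, np.nan) for cell in cells}
    tstat = {cell: np.full(n_edges, np.nan) for cell in cells}

    if method == "mean":
        for cell, mask in cell_masks.items():
            if mask.sum() < 2:
                continue
            zc = Z[mask]
            est[cell] = zc.mean(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tt = stats.ttest_1samp(zc, 0.0, axis=0)
            tstat[cell] = tt.statistic
            pval[cell] = tt.pvalue
    elif method == "lme":
        exog = pd.get_dummies(
            pd.DataFrame({"group": meta["group"].astype(str),
                          "week": meta["week"].astype(str)}),
            drop_first=True, dtype=float)
        groups_d = [c for c in exog.columns if c.startswith("group_")]
        weeks_d = [c for c in exog.columns if c.startswith("week_")]
        for g in groups_d:
            for w in weeks_d:
                exog[f"{g}:{w}"] = exog[g] * exog[w]
        exog.insert(0, "const", 1.0)
        X = exog.to_numpy()
        k = X.shape[1]
        subj = meta["subject"].to_numpy()
        rows = {cell: X[mask][0] for cell, mask in cell_masks.items() if mask.any()}
        valid = [cell for cell, mask in cell_masks.items() if mask.sum() >= 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for e in range(n_edges):
                try:
                    fit = MixedLM(Z[:, e], X, groups=subj).fit(reml=True,
                                                               method="lbfgs")
                    beta = fit.fe_params
                    cov = np.asarray(fit.cov_params())[:k, :k]
                except (np.linalg.LinAlgError, ValueError):
                    beta, cov = None, None
                for cell in valid:
                    row = rows[cell]
                    if beta is not None:
                        mu = float(row @ beta)
                        se = math.sqrt(max(float(row @ cov @ row), 1e-300))
                        z = mu / se
                        est[cell][e] = mu
                        tstat[cell][e] = z
                        pval[cell][e] = 2.0 * stats.norm.sf(abs(z))
                    else:  # singular fit: fall back to the cell mean
                        zc = Z[cell_masks[cell], e]
                        est[cell][e] = zc.mean()
                        tt = stats.ttest_1samp(zc, 0.0)
                        tstat[cell][e] = tt.statistic
                        pval[cell][e] = tt.pvalue
    else:
        raise ValueError(f"unknown group method {method!r}")

    out: dict[tuple[str, int], ConnectivityNetwork] = {}
    for cell in cells:
        n_obs = int(cell_masks[cell].sum())
        r = np.eye(nc)
        t = np.full((nc, nc), np.inf)
        p = np.zeros((nc, nc))
        q = np.zeros((nc, nc))
        r[iu] = np.tanh(est[cell])
        r[(iu[1], iu[0])] = r[iu]
        t[iu] = tstat[cell]
        t[(iu[1], iu[0])] = t[iu]
        p[iu] = pval[cell]
        p[(iu[1], iu[0])] = p[iu]
        finite = np.isfinite(pval[cell])
        qf = np.full(n_edges, np.nan)
        if finite.any():
            qf[finite] = benjamini_hochberg(pval[cell][finite])
        q[iu] = qf
        q[(iu[1], iu[0])] = q[iu]
        prov = {"group": cell[0], "week": cell[1], "level": "group",
                "method": method, "n_scans": n_obs,
                "excluded": n_obs < 2}
        out[cell] = ConnectivityNetwork(channels=channels, r=r, t=t, p=p, q=q,
                                        n_effective=n_obs, hb_type=hb_type,
                                        provenance=prov)
    return out


# ---------------------------------------------------------------- network similarity

def compute_dsi(net_a: ConnectivityNetwork, net_b: ConnectivityNetwork,
                q_threshold: float = 0.05) -> float:
    """Differential symmetry index between two binarized networks.

    Both networks are thresholded at q < q_threshold; the observed edge-set
    symmetry S = |A ∩ B| / |A ∪ B| is compared with the overlap expected
    from two independent random graphs of the same densities,
    E[S] = dA dB / (dA + dB - dA dB). DSI = S - E[S]; positive values mean
    more shared structure than density alone explains. Empty graphs give 0.
    """
    if net_a.channels != net_b.channels:
        raise ValueError("networks must share the same channel set")
    a = net_a.upper_triangle("q") < q_threshold
    b = net_b.upper_triangle("q") < q_threshold
    union = np.logical_or(a, b).sum()
    inter = np.logical_and(a, b).sum()
    s_obs = inter / union if union else 0.0
    m = a.size
    da, db = a.sum() / m, b.sum() / m
    denom = da + db - da * db
    s_exp = (da * db / denom) if denom > 0 else 0.0
    return float(s_obs - s_exp)
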