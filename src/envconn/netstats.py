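"""Network-level aggregation and group statistics.

ROI x ROI Fisher-z matrices are averaged into 6 x 6 network matrices
(diagonal = within-network).  Group inference covers the pre/post session
contrast (two-level repeated-measures ANOVA, equivalently the squared paired
t), Pearson brain-behavior correlations, Benjamini-Hochberg FDR over the
two declared families (6 motor pairs of interest; all 21 pairs), and the
exact power of the two-sided test of zero correlation under bivariate
normality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats
from statsmodels.stats.multitest import multipletests

from .connectivity import BandConnectivity
from .rois import NETWORKS, NetworkTable, all_network_pairs, roi_pairs_for


@dataclass
class NetworkConnectivity:
    """6 x 6 network matrix per band (diagonal holds within-network values)."""

    values: dict[str, np.ndarray]
    networks: tuple[str, ...] = NETWORKS
    subject: str = ""
    session: str = ""
    excluded_pairs: dict[str, int] = field(default_factory=dict)

    def get(self, band: str, net_a: str, net_b: str) -> float:
        i = self.networks.index(net_a)
        j = self.networks.index(net_b)
        return float(self.values[band][i, j])


def aggregate_networks(
    band_conn: BandConnectivity, table: NetworkTable
) -> NetworkConnectivity:
    """Average ROI-pair z values within and between networks.

    within(N) is the mean over the |N|(|N|-1)/2 pairs inside N; between(A,B)
    the mean over all |A|x|B| cross pairs.  NaN sentinels are excluded and
    counted.
    """
    if tuple(band_conn.roi_names) != tuple(table.names):
        raise ValueError("ROI labels of the connectivity matrix do not match the table")
    networks = tuple(dict.fromkeys(table.networks))
    values: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for band, mat in band_conn.z.items():
        out = np.full((len(networks), len(networks)), np.nan)
        n_excl = 0
        for a, net_a in enumerate(networks):
            for b in range(a, len(networks)):
                net_b = networks[b]
                if net_a == net_b and len(table.members(net_a)) < 2:
                    raise ValueError(
                        f"network {net_a} has fewer than 2 ROIs; "
                        "within-network value undefined"
                    )
                pairs = roi_pairs_for(table, net_a, net_b)
                vals = np.array([mat[i, j] for i, j in pairs])
                finite = np.isfinite(vals)
                n_excl += int((~finite).sum())
                if finite.any():
                    out[a, b] = out[b, a] = vals[finite].mean()
        values[band] = out
        excluded[band] = n_excl
    return NetworkConnectivity(
        values=values,
        networks=networks,
        subject=band_conn.subject,
        session=band_conn.session,
        excluded_pairs=excluded,
    )


def session_effect(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, tuple[int, int], float, float]:
    """Two-level RM-ANOVA for the pre/post contrast over paired subjects.

    Returns (F, (1, n-1), p, mean(post - pre)).  F equals the squared paired
    t statistic; subjects with a missing session are dropped.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[ok], post[ok]
    n = len(pre)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    d = post - pre
    if np.all(d == d[0]) and d[0] == 0.0:
        return 0.0, (1, n - 1), 1.0, 0.0
    t, p = stats.ttest_rel(post, pre)
    return float(t) ** 2, (1, n - 1), float(p), float(np.mean(d))


def brain_behavior_correlation(
    values: np.ndarray, covariate: np.ndarray
) -> tuple[float, float, int]:
    """Pearson r with two-tailed p over listwise-complete subject pairs."""
    values = np.asarray(values, float)
    covariate = np.asarray(covariate, float)
    ok = np.isfinite(values) & np.isfinite(covariate)
    x, y = values[ok], covariate[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan, n
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p values and rejection flags."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    flags, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, flags


# ---------------------------------------------------------------------------
# exact power of the zero-correlation test
# ---------------------------------------------------------------------------

def sample_correlation_pdf(r, rho: float, n: int):
    """Exact density of the sample Pearson r for bivariate normal data."""
    r = np.asarray(r, float)
    log_c = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2 * np.log1p(-rho**2)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
    )
    with np.errstate(divide="ignore"):
        log_f = (
            log_c
            + (n - 4) / 2 * np.log1p(-(r**2))
            - (n - 1.5) * np.log1p(-rho * r)
        )
    return np.exp(log_f) * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2)


def correlation_critical_r(n: int, alpha: float) -> float:
    """Two-sided critical |r| from the null t-transform t = r sqrt(n-2)/sqrt(1-r^2)."""
    t_crit = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def correlation_power_exact(rho: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided exact test of zero Pearson correlation.

    The rejection region |r| > r_crit comes from the exact null via the
    t-transform; the power integrates the exact sampling density of r given
    (rho, n) over that region by adaptive quadrature.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rc = correlation_critical_r(n, alpha)
    lo, _ = integrate.quad(
        sample_correlation_pdf, -1.0, -rc, args=(rho, n), epsabs=1e-10, epsrel=1e-9
    )
    hi, _ = integrate.quad(
        sample_correlation_pdf, rc, 1.0, args=(rho, n), epsabs=1e-10, epsrel=1e-9
    )
    return lo + hi


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

def session_effect_report(
    pre: list[NetworkConnectivity],
    post: list[NetworkConnectivity],
    bands: list[str],
) -> pd.DataFrame:
    """Session RM-ANOVA for every network pair and band, with both FDR families."""
    rows = []
    for band in bands:
        for net_a, net_b in all_network_pairs():
            x = np.array([c.get(band, net_a, net_b) for c in pre])
            y = np.array([c.get(band, net_a, net_b) for c in post])
            try:
                F, df, p, direction = session_effect(x, y)
                df_str = f"({df[0]},{df[1]})"
            except ValueError:  # cohort too small: sentinel row, never silent
                F, df_str, p, direction = np.nan, "", np.nan, np.nan
            rows.append({
                "band": band,
                "pair": f"{net_a}-{net_b}",
                "stat": F,
                "df_or_n": df_str,
                "p_raw": p,
                "direction": direction,
            })
    return _attach_fdr(pd.DataFrame(rows))


def brain_behavior_report(
    conn: list[NetworkConnectivity],
    covariate: np.ndarray,
    bands: list[str],
    label: str,
) -> pd.DataFrame:
    """Pearson correlation of a behavioral covariate with network values."""
    rows = []
    for band in bands:
        for net_a, net_b in all_network_pairs():
            vals = np.array([c.get(band, net_a, net_b) for c in conn])
            try:
                r, p, n = brain_behavior_correlation(vals, covariate)
            except ValueError:
                r, p, n = np.nan, np.nan, 0
            rows.append({
                "band": band,
                "pair": f"{net_a}-{net_b}",
                "stat": r,
                "df_or_n": str(n),
                "p_raw": p,
                "covariate": label,
            })
    return _attach_fdr(pd.DataFrame(rows))


def _attach_fdr(df: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """BH-adjusted p per band over the interest-6 and all-21 families."""
    interest = {"MOT-MOT"} | {f"MOT-{n}" for n in NETWORKS if n != "MOT"} \
        | {f"{n}-MOT" for n in NETWORKS if n != "MOT"}
    df = df.copy()
    df["p_fdr6"] = np.nan
    df["p_fdr21"] = np.nan
    for band in df["band"].unique():
        sel21 = df["band"] == band
        ok = sel21 & np.isfinite(df["p_raw"])
        if ok.any():
            df.loc[ok, "p_fdr21"] = fdr_correct(df.loc[ok, "p_raw"].to_numpy(), q)[0]
        sel6 = ok & df["pair"].isin(interest)
        if sel6.any():
            df.loc[sel6, "p_fdr6"] = fdr_correct(df.loc[sel6, "p_raw"].to_numpy(), q)[0]
    return df
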