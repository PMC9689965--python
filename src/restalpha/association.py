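"""Association between resting-state features and MI performance.

Channel-wise Pearson correlation maps per state/band/feature, a
repeated-measures contrast of |r| across frequency bands (channels as the
repeated units, with Mauchly's sphericity test and the Greenhouse-Geisser
correction, followed by pairwise paired t-tests), channel-pair feature
averages, and Welch t-tests between the H/M/L performance groups.

Significance is reported uncorrected (stars at p < 0.05); an optional
Benjamini-Hochberg adjustment across channels is available but off by
default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: The channel pair whose eyes-open alpha value summarizes each feature.
DEFAULT_CHANNEL_PAIRS = {
    "RPL": ("C3", "C4"),
    "PSE": ("C4", "Cp4"),
    "LZC": ("C3", "Cp4"),
}

P_FLOOR = 1e-300


@dataclass
class ContrastReport:
    mauchly_p: float
    gg_epsilon: float
    gg_p: float
    pairwise: pd.DataFrame  # columns band_a, band_b, t, p


def _pearson(x: np.ndarray, y: np.ndarray):
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(max(p, P_FLOOR))


def correlation_map(
    feature_table: pd.DataFrame,
    performance: pd.DataFrame,
    measure: str = "acc_4class_mean",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson r and two-sided p per (state, band, channel, feature) cell.

    Subjects are aligned by id; those missing from either table are excluded
    listwise.  Zero-variance cells yield NaN (undefined), never a silent 0.
    """
    perf = performance.set_index("subject")[measure]
    common = sorted(set(feature_table["subject"]) & set(perf.index))
    if len(common) < 3:
        raise ValueError("need at least 3 common subjects for a correlation map")
    perf = perf.loc[common]

    wide = feature_table.pivot_table(
        index="subject", columns=["state", "band", "channel", "feature"], values="value"
    ).loc[common]
    y = perf.to_numpy(dtype=float)
    rows = []
    for col in wide.columns:
        r, p = _pearson(wide[col].to_numpy(dtype=float), y)
        rows.append((*col, r, p, len(common)))
    cmap = pd.DataFrame(
        rows, columns=["state", "band", "channel", "feature", "r", "p", "n"]
    )
    cmap.attrs["measure"] = measure
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = cmap["p"].notna()
        adj = np.full(len(cmap), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(cmap.loc[ok, "p"], method="fdr_bh")[1]
        cmap["p_adj"] = adj
    return cmap


def band_contrast(
    cmap: pd.DataFrame, feature: str, state: str
) -> ContrastReport:
    """Repeated-measures contrast of |r| across bands, channels as units."""
    import pingouin as pg

    sub = cmap[(cmap["feature"] == feature) & (cmap["state"] == state)]
    wide = sub.pivot(index="channel", columns="band", values="r").abs()
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 channels for the band contrast")
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 bands for the band contrast")

    long = (
        wide.reset_index()
        .melt(id_vars="channel", var_name="band", value_name="abs_r")
        .dropna()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spher = pg.sphericity(long, dv="abs_r", within="band", subject="channel")
        aov = pg.rm_anova(
            long, dv="abs_r", within="band", subject="channel", correction=True
        )
    gg_eps = float(aov.loc[0, "eps"])
    if "p_GG_corr" in aov.columns and not np.isnan(aov.loc[0, "p_GG_corr"]):
        gg_p = float(aov.loc[0, "p_GG_corr"])
    else:  # sphericity not rejected -> uncorrected p applies
        gg_p = float(aov.loc[0, "p_unc"])

    pairs = []
    for a, b in itertools.combinations(sorted(wide.columns), 2):
        t, p = stats.ttest_rel(wide[a], wide[b])
        pairs.append((a, b, float(t), float(max(p, P_FLOOR))))
    return ContrastReport(
        mauchly_p=float(max(spher.pval, P_FLOOR)),
        gg_epsilon=gg_eps,
        gg_p=float(max(gg_p, P_FLOOR)),
        pairwise=pd.DataFrame(pairs, columns=["band_a", "band_b", "t", "p"]),
    )


def channel_pair_average(
    feature_table: pd.DataFrame,
    pairs: dict[str, tuple[str, str]] | None = None,
    band: str = "alpha",
    state: str = "eyes_open",
) -> pd.DataFrame:
    """Per-subject scalar per feature: mean of the feature's two channels.

    Defaults to the eyes-open alpha values on the canonical pairs (C3/C4 for
    RPL, C4/Cp4 for PSE, C3/Cp4 for LZC).  Returns subjects x features.
    """
    pairs = pairs or DEFAULT_CHANNEL_PAIRS
    sub = feature_table[(feature_table["band"] == band) & (feature_table["state"] == state)]
    out = {}
    for feat, (ch_a, ch_b) in pairs.items():
        cols = {}
        for ch in (ch_a, ch_b):
            cell = sub[(sub["feature"] == feat) & (sub["channel"] == ch)]
            if cell.empty:
                raise ValueError(f"channel {ch!r} missing from the feature table")
            cols[ch] = cell.set_index("subject")["value"]
        out[feat] = (cols[ch_a] + cols[ch_b]) / 2.0
    df = pd.DataFrame(out)
    df.index.name = "subject"
    return df


def group_contrasts(
    pair_features: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Welch independent t-tests between performance groups, per feature.

    Compares H-M, H-L and M-L; a group with fewer than 2 subjects is skipped
    with a warning.
    """
    groups = groups.reindex(pair_features.index)
    rows = []
    for feat in pair_features.columns:
        for ga, gb in (("H", "M"), ("H", "L"), ("M", "L")):
            xa = pair_features.loc[groups == ga, feat].dropna()
            xb = pair_features.loc[groups == gb, feat].dropna()
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"skipping {ga} vs {gb} for {feat}: a group has < 2 subjects"
                )
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append((feat, ga, gb, float(t), float(max(p, P_FLOOR)), len(xa), len(xb)))
    return pd.DataFrame(
        rows, columns=["feature", "group_a", "group_b", "t", "p", "n_a", "n_b"]
    )
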