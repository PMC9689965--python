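"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities through different
algorithms/code paths than the package (brute-force LZ76 parsing via
substring search, whitening-based CSP eigendecomposition, textbook Pearson
formula) so that agreement is informative.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg


# ---------------------------------------------------------------------------
# oracle: brute-force LZ76 parser (longest-match via bytes substring search)


def lz76_brute(symbols) -> int:
    s = np.asarray(symbols, dtype=np.uint8).tobytes()
    n = len(s)
    if n == 0:
        return 0
    c = 1
    i = 1
    while i < n:
        k = 1
        # grow the candidate phrase while it still occurs inside the prefix
        # (occurrences may overlap the phrase itself)
        while i + k <= n and s.find(s[i : i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


# ---------------------------------------------------------------------------
# oracle: CSP filters through explicit whitening (two plain eigh calls)


def csp_filters_whitening(s_class: np.ndarray, s_rest: np.ndarray, n_filters: int):
    composite = s_class + s_rest
    d, v = np.linalg.eigh(composite)
    whitener = v @ np.diag(1.0 / np.sqrt(d)) @ v.T
    m = whitener @ s_class @ whitener
    evals, u = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1][:n_filters]
    w = (whitener @ u[:, order]).T
    return w


def align_filters(w: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Normalize rows to unit norm and the sign convention of ``ref``."""
    w = w / np.linalg.norm(w, axis=1, keepdims=True)
    ref = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    signs = np.sign(np.sum(w * ref, axis=1))
    signs[signs == 0] = 1.0
    return w * signs[:, None]


# ---------------------------------------------------------------------------
# oracle: Pearson correlation from the covariance formula


def pearson_brute(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


# ---------------------------------------------------------------------------
# expensive shared cohorts (session-scoped: computed once per test run)


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=100 cohort with planted_rho=0.5, scored through the full pipeline.

    Used by the parameter-recovery checks; the relative-power feature table
    is computed for all channels/bands (entropy and complexity are checked
    on their own smaller fixtures elsewhere).
    """
    from restalpha import association, synthetic
    from restalpha.pipeline import PipelineConfig, feature_table, performance_table

    cfg = PipelineConfig(
        cohort=synthetic.CohortSpec(n_subjects=100, planted_rho=0.5, seed=42)
    )
    gt = synthetic.ground_truth(cfg.cohort)
    feats = feature_table(cfg, feature_names=("RPL",))
    perf = performance_table(cfg)
    cmap = association.correlation_map(feats, perf)
    return {"cfg": cfg, "gt": gt, "features": feats, "performance": perf, "cmap": cmap}


@pytest.fixture(scope="session")
def screening_cohort():
    """Screening-calibrated cohort (H distinct, M ~ L), n=105."""
    from restalpha import association, synthetic
    from restalpha.pipeline import PipelineConfig, feature_table

    spec = synthetic.screening_cohort_spec(n_subjects=105, seed=7)
    cfg = PipelineConfig(cohort=spec)
    gt = synthetic.ground_truth(spec)
    feats = feature_table(cfg, channels=("C3", "C4", "Cp4"))
    pair = association.channel_pair_average(feats)
    groups = gt.set_index("subject")["intended_group"]
    return {"spec": spec, "gt": gt, "pair_features": pair, "groups": groups}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
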