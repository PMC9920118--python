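"""Monte-Carlo-dropout inference: stochastic forward passes, predictive
moments and uncertainty-based window rejection.

Running the dropout-equipped network T times at test time approximates the
Bayesian predictive distribution: the predictive mean is the sample mean of
the passes and the predictive variance is the model-precision term tau^-1
plus the population second moment minus the squared mean.  tau^-1 defaults
to zero (pure between-pass variance) because no numerical precision
constant is published; it is config-exposed.

Whole windows are rejected by a top-fraction rule on a scalar score that
combines both output heads (rate-head variance plus the mean per-sample
signal variance), so the most uncertain ``reject_fraction`` of windows is
dropped before error metrics are computed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import net as _net
from .respsig import windows_to_arrays
from .rrtools import mae as _mae, rmse as _rmse

__all__ = ["BayesConfig", "UncertaintySummary", "mc_forward",
           "predictive_moments", "reject_uncertain",
           "sweep_inference_samples", "mc_predict"]


@dataclass(frozen=True)
class BayesConfig:
    """MC-dropout configuration.

    ``T`` stochastic passes; ``tau_inv`` additive model-precision term of
    the predictive variance; ``dropout_p`` Bernoulli drop probability used
    during the passes (None = keep the model's own); ``reject_fraction``
    fraction of most-uncertain windows to discard.
    """

    T: int = 10
    tau_inv: float = 0.0
    dropout_p: float | None = 0.1
    reject_fraction: float = 0.037
    seed: int = 0

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.tau_inv < 0:
            raise ValueError("tau_inv must be >= 0")
        if not 0.0 <= self.reject_fraction < 1.0:
            raise ValueError("reject_fraction must be in [0, 1)")
        if self.dropout_p is not None and not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass
class UncertaintySummary:
    """Predictive mean/variance per output plus a scalar rejection score."""

    mean_resp: np.ndarray
    var_resp: np.ndarray
    mean_rr: float
    var_rr: float
    score: float

    def __post_init__(self):
        if np.any(np.asarray(self.var_resp) < 0) or self.var_rr < 0:
            raise ValueError("variances must be non-negative")


def mc_forward(model, window, cfg: BayesConfig) -> list[_net.ModelOutput]:
    """T seeded stochastic forward passes with dropout active.

    Raises a configuration error when the model carries no dropout (its own
    probability is zero and no override is given).
    """
    if cfg.dropout_p is None and model.cfg.dropout_p == 0:
        raise ValueError("model has no dropout; MC inference is undefined")
    p = model.cfg.dropout_p if cfg.dropout_p is None else cfg.dropout_p
    old = _net.set_dropout_p(model, p)
    try:
        seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.T)
        outs = [_net.forward(model, window, mc_dropout=True,
                             rng_seed=int(s), with_attention=False)
                for s in seeds]
    finally:
        _net.restore_dropout_p(model, old)
    return outs


def predictive_moments(samples, cfg: BayesConfig, rr_scale: float = 1.0):
    """Predictive mean and variance from T stochastic passes.

    variance = tau_inv + (1/T) * sum f^2 - mean^2 per output element
    (population moments, matching the second-moment form exactly).

    The scalar rejection score adds the two heads' variances in the
    network's native output units: the rate head's variance is divided by
    ``rr_scale**2`` (the stored de-standardisation factor) so it is
    commensurate with the z-scaled signal variance instead of swamping it.
    Returns one :class:`UncertaintySummary` for single-window samples or a
    list for batched samples.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 stochastic samples")
    resp = np.stack([np.atleast_2d(s.resp) for s in samples])   # (T, N, L)
    rr = np.stack([np.atleast_1d(s.rr) for s in samples])       # (T, N)
    mean_resp = resp.mean(axis=0)
    var_resp = cfg.tau_inv + (resp ** 2).mean(axis=0) - mean_resp ** 2
    mean_rr = rr.mean(axis=0)
    var_rr = cfg.tau_inv + (rr ** 2).mean(axis=0) - mean_rr ** 2
    var_resp = np.maximum(var_resp, 0.0) + 0.0
    var_rr = np.maximum(var_rr, 0.0)
    out = [UncertaintySummary(mean_resp=mean_resp[i], var_resp=var_resp[i],
                              mean_rr=float(mean_rr[i]),
                              var_rr=float(var_rr[i]),
                              score=float(var_rr[i] / rr_scale ** 2
                                          + var_resp[i].mean()))
           for i in range(mean_resp.shape[0])]
    return out[0] if np.ndim(samples[0].resp) == 1 else out


def reject_uncertain(summaries, cfg: BayesConfig):
    """Split window indices into (kept, rejected) by the top-fraction rule:
    the ``reject_fraction`` highest scores are rejected (ties broken by
    window order)."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to filter")
    scores = np.array([s.score for s in summaries])
    n = len(scores)
    n_rej = int(round(cfg.reject_fraction * n))
    if n_rej == 0:
        return np.arange(n), np.empty(0, dtype=int)
    order = np.argsort(scores, kind="stable")
    rejected = np.sort(order[-n_rej:])
    kept = np.sort(order[:-n_rej])
    return kept, rejected


def mc_predict(model, X: np.ndarray, cfg: BayesConfig):
    """Batched convenience wrapper: windows (N,3,L) -> list of summaries.

    Over a batch, the rejection score gives the two heads equal
    statistical voice by standardising each variance component (z-score
    across the batch) before summation; otherwise the head with the larger
    variance spread (the rate head, in practice) would decide every
    rejection on its own.  The combined score is shifted by its batch
    minimum so it stays non-negative; the quantile rejection rule only
    uses its ordering.
    """
    samples = mc_forward(model, X, cfg)
    out = predictive_moments(samples, cfg,
                             rr_scale=float(model.rr_norm["scale"]))
    if not isinstance(out, list):
        return [out]
    if len(out) >= 2:
        vrr = np.array([s.var_rr for s in out])
        vresp = np.array([s.var_resp.mean() for s in out])
        eps = 1e-12
        combined = (vrr - vrr.mean()) / (vrr.std() + eps) \
            + (vresp - vresp.mean()) / (vresp.std() + eps)
        combined -= combined.min()
        for s, c in zip(out, combined):
            s.score = float(c)
    return out


def sweep_inference_samples(model, windows, T_list, seed: int = 0,
                            cfg: BayesConfig | None = None) -> pd.DataFrame:
    """Trade-off table: for each inference-sample count T, the kept-set
    average-RR MAE/RMSE, the rejection percentage and the wall time."""
    T_list = list(T_list)
    if any(t < 2 or t > 64 for t in T_list):
        raise ValueError("T values must lie in 2..64")
    base = cfg or BayesConfig(seed=seed)
    X, _, y_rr = windows_to_arrays(windows)
    rows = []
    for T in T_list:
        c = BayesConfig(T=T, tau_inv=base.tau_inv, dropout_p=base.dropout_p,
                        reject_fraction=base.reject_fraction, seed=seed)
        t0 = time.perf_counter()
        summaries = mc_predict(model, X, c)
        kept, rejected = reject_uncertain(summaries, c)
        wall = time.perf_counter() - t0
        pred = np.array([summaries[i].mean_rr for i in kept])
        rows.append({"T": T,
                     "avg_rr_mae": _mae(pred, y_rr[kept]),
                     "avg_rr_rmse": _rmse(pred, y_rr[kept]),
                     "pct_rejected": 100.0 * len(rejected) / len(summaries),
                     "wall_time_s": wall})
    return pd.DataFrame(rows)
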