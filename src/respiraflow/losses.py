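"""Training objectives: smooth L1, multitask sum, attention-map statistics,
attention-transfer loss and the distillation imitation loss.

Reduction convention: smooth-L1 terms are summed over elements and averaged
over the batch (so learning rates are batch-size independent).  Every
function accepts either autodiff tensors (returning a graph node) or plain
arrays (returning a float).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import core
from .nn.core import Tensor

__all__ = ["KDWeights", "smooth_l1", "multitask_loss", "attention_map",
           "attention_transfer_loss", "kd_loss"]


@dataclass(frozen=True)
class KDWeights:
    """Distillation configuration.

    ``alpha`` mixes the ground-truth loss (weight alpha) with the
    teacher-imitation loss (weight 1 - alpha); ``at_layers`` names the
    feature blocks whose attention maps are matched during the
    attention-transfer phase (None pairs every block shared by teacher and
    student).
    """

    alpha: float = 0.94
    at_layers: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.at_layers is not None and len(self.at_layers) == 0:
            raise ValueError("at_layers must be non-empty when given")


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _ret(out: Tensor, any_tensor: bool):
    return out if any_tensor else float(out.data)


def smooth_l1(pred, target):
    """Smooth-L1 (Huber-style) loss: 0.5 d^2 for |d| < 1, |d| - 0.5
    otherwise; summed over elements, averaged over the batch (axis 0 for
    inputs with 2+ dimensions)."""
    p, is_t = _as_tensor(pred)
    t = target.data if isinstance(target, Tensor) else np.asarray(target,
                                                                  dtype=float)
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {t.shape}")
    n_batch = p.data.shape[0] if p.data.ndim >= 2 else 1
    out = core.smooth_l1(p, t) * (1.0 / n_batch)
    return _ret(out, is_t)


def multitask_loss(resp_hat, resp_gt, rr_hat, rr_gt):
    """Total objective: signal-reconstruction term plus rate term."""
    r, t1 = _as_tensor(resp_hat)
    q, t2 = _as_tensor(rr_hat)
    out = smooth_l1(r, resp_gt) + smooth_l1(q, rr_gt)
    return _ret(out, t1 or t2) if isinstance(out, Tensor) else out


def attention_map(A):
    """Activation-energy map: per-position sum over channels of squared
    magnitudes.  (C, L) -> (L,); (N, C, L) -> (N, L)."""
    a, is_t = _as_tensor(A)
    if a.data.ndim not in (2, 3) or a.data.size == 0:
        raise ValueError("attention_map expects a non-empty (C,L) or (N,C,L) map")
    axis = 0 if a.data.ndim == 2 else 1
    out = core.sum_all(core.square(a), axis=axis)
    return out if is_t else out.data


def _normalise_map(q: Tensor, eps: float) -> Tensor:
    """Row-normalise (N, L) maps to unit L2 norm with an epsilon guard."""
    if np.any(np.linalg.norm(q.data, axis=-1) < eps):
        warnings.warn("attention map with (near-)zero norm; epsilon guard active")
    norm = core.sqrt_eps(core.sum_all(core.square(q), axis=-1,
                                      keepdims=True), eps * eps)
    return q * core.reciprocal(norm)


def attention_transfer_loss(student_maps, teacher_maps, eps: float = 1e-8):
    """Sum over layer pairs of the L2 distance between L2-normalised
    vectorised attention maps; invariant to positive rescaling of either
    map.  Teacher maps of mismatched length are linearly interpolated to
    the student length before vectorisation."""
    student_maps = list(student_maps)
    teacher_maps = list(teacher_maps)
    if len(student_maps) != len(teacher_maps) or not student_maps:
        raise ValueError("need equally many (non-zero) student/teacher maps")
    total = None
    any_tensor = False
    for qs, qt in zip(student_maps, teacher_maps):
        s, is_t = _as_tensor(qs)
        any_tensor |= is_t
        if s.data.ndim == 1:
            s = s.reshape(1, -1)
        t = qt.data if isinstance(qt, Tensor) else np.asarray(qt, dtype=float)
        if t.ndim == 1:
            t = t[None, :]
        Ls = s.data.shape[-1]
        if t.shape[-1] != Ls:
            xi = np.linspace(0.0, 1.0, t.shape[-1])
            xo = np.linspace(0.0, 1.0, Ls)
            t = np.stack([np.interp(xo, xi, row) for row in t])
        # same epsilon-guarded normalisation as the tensor path
        tn = t / np.sqrt((t ** 2).sum(axis=-1, keepdims=True) + eps * eps)
        diff = _normalise_map(s, eps) - Tensor(tn)
        per_sample = core.sqrt_eps(core.sum_all(core.square(diff), axis=-1),
                                   1e-30)
        term = core.mean_all(per_sample)
        total = term if total is None else total + term
    return _ret(total, any_tensor)


def kd_loss(student_out, teacher_out, ground_truth, w: KDWeights):
    """Distillation objective: alpha * L(gt, student) +
    (1 - alpha) * L(teacher, student), each a multitask smooth-L1 over both
    heads.  ``*_out`` are (resp, rr) pairs; teacher outputs are treated as
    constants."""
    s_resp, t1 = _as_tensor(student_out[0])
    s_rr, t2 = _as_tensor(student_out[1])
    te_resp = teacher_out[0].data if isinstance(teacher_out[0], Tensor) \
        else np.asarray(teacher_out[0], dtype=float)
    te_rr = teacher_out[1].data if isinstance(teacher_out[1], Tensor) \
        else np.asarray(teacher_out[1], dtype=float)
    gt_loss = multitask_loss(s_resp, ground_truth[0], s_rr, ground_truth[1])
    im_loss = multitask_loss(s_resp, te_resp, s_rr, te_rr)
    out = gt_loss * w.alpha + im_loss * (1.0 - w.alpha)
    return _ret(out, t1 or t2) if isinstance(out, Tensor) else out
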