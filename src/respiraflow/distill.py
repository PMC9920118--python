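"""Training orchestration: teacher training, attention-transfer
pre-training of the student, and distillation fine-tuning.

The three phases run in a fixed order — (1) the teacher minimises the
multitask smooth-L1 objective; (2) the student matches the frozen
teacher's per-block attention (activation-energy) maps; (3) the student
fine-tunes on the convex combination of ground-truth and
teacher-imitation losses (mixing weight alpha, default 0.94).  Learning
rates follow dataset-keyed piecewise-constant schedules (1e-2 for the
first 20 epochs, then 1e-4 or 1e-3).  Every phase is fully seeded:
identical configuration gives bit-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import losses, net as _net
from .nn.core import Tensor
from .nn.optim import Adam
from .respsig import windows_to_arrays
from .rrtools import mae as _mae

__all__ = ["TrainConfig", "lr_at", "train_teacher", "pretrain_student_at",
           "train_student_kd", "select_student_size"]

# canonical ordering of feature blocks for attention transfer
_TAG_ORDER = ([f"enc{i}" for i in range(1, 6)] + ["bneck"]
              + [f"dec{i}" for i in range(1, 6)]
              + [f"head{i}" for i in range(1, 5)])


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the reference setup:
    100 epochs, batch 128, Adam, 80:20 split)."""

    epochs: int = 100
    batch_size: int = 128
    dataset_key: str = "ir"            # selects the LR schedule
    split: float = 0.8
    split_mode: str = "window"
    at_epochs: int = 20                # attention-transfer pre-training phase
    at_lr: float | None = None         # None = dataset schedule
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 < self.split < 1:
            raise ValueError("split must be a fraction in (0, 1)")


def lr_at(epoch: int, dataset_key: str = "ir") -> float:
    """Piecewise-constant learning rate: 1e-2 for epochs <= 20, then 1e-4
    (key ``dalia``) or 1e-3 (key ``ir``).  Unknown keys fall back to the
    ``ir`` schedule with a warning."""
    if epoch < 1:
        raise ValueError("epoch numbering starts at 1")
    key = dataset_key.lower()
    if key not in ("dalia", "ir"):
        warnings.warn(f"unknown dataset key {dataset_key!r}; using 'ir' schedule")
        key = "ir"
    if epoch <= 20:
        return 1e-2
    return 1e-4 if key == "dalia" else 1e-3


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i:i + batch_size]


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"{what} became non-finite at epoch {epoch}; "
            "lower the learning rate or inspect the input windows")


def train_teacher(windows, cfg: TrainConfig | None = None,
                  arch_cfg: _net.ArchConfig | None = None,
                  model: _net.Module | None = None):
    """Train the multitask model on signal windows.

    Returns ``(model, metrics)`` where metrics is a per-epoch DataFrame
    with columns epoch / lr / train_loss.  Raises on non-finite loss.
    """
    cfg = cfg or TrainConfig()
    model = model or _net.build_teacher(arch_cfg or _net.teacher_config())
    X, y_resp, y_rr = windows_to_arrays(windows)
    if len(X) < cfg.batch_size:
        warnings.warn("fewer windows than one batch; training on one batch")
    # standardise the rate target; the affine inverse is stored on the model
    offset, scale = float(y_rr.mean()), float(max(y_rr.std(), 1e-6))
    model.rr_norm = {"offset": np.array(offset), "scale": np.array(scale)}
    y_rr = (y_rr - offset) / scale
    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    opt = Adam(model.parameters(), lr=lr_at(1, cfg.dataset_key))
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_at(epoch, cfg.dataset_key)
        total, nb = 0.0, 0
        for b in _batches(len(X), cfg.batch_size, shuffle_rng):
            resp, rr, _, _ = model(Tensor(X[b]), training=True, rng=drop_rng)
            loss = losses.multitask_loss(resp, y_resp[b][:, None, :],
                                         rr, y_rr[b][:, None])
            _check_finite(float(loss.data), "training loss", epoch)
            loss.backward()
            opt.step()
            opt.zero_grad()
            total += float(loss.data)
            nb += 1
        rows.append({"epoch": epoch, "lr": opt.lr, "train_loss": total / nb})
    return model, pd.DataFrame(rows)


def _teacher_maps(teacher, X: np.ndarray, tags) -> dict:
    """Frozen-teacher attention maps as constants."""
    _, _, _, feats = teacher(Tensor(X), training=False)
    return {t: losses.attention_map(feats[t].data) for t in tags}


def _shared_tags(student, teacher, at_layers=None) -> list[str]:
    xs = np.zeros((1, student.cfg.in_channels, student.cfg.input_len))
    _, _, _, sf = student(Tensor(xs), training=False)
    _, _, _, tf = teacher(Tensor(xs), training=False)
    shared = [t for t in _TAG_ORDER if t in sf and t in tf]
    if at_layers is not None:
        missing = set(at_layers) - set(shared)
        if missing:
            raise ValueError(f"attention-transfer layers not shared: {missing}")
        shared = [t for t in shared if t in at_layers]
    return shared


def pretrain_student_at(student, teacher, windows,
                        w: losses.KDWeights | None = None,
                        cfg: TrainConfig | None = None):
    """Phase 2: optimise the student on the attention-transfer loss alone,
    matching its activation-energy maps to the frozen teacher's.

    Returns ``(student, metrics)`` with a per-epoch ``at_loss`` column.
    """
    w = w or losses.KDWeights()
    cfg = cfg or TrainConfig()
    tags = _shared_tags(student, teacher, w.at_layers)
    X, _, _ = windows_to_arrays(windows)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed + 1).generate_state(1)[0])
    opt = Adam(student.parameters(), lr=cfg.at_lr or lr_at(21, cfg.dataset_key))
    rows = []
    for epoch in range(1, cfg.at_epochs + 1):
        total, nb = 0.0, 0
        for b in _batches(len(X), cfg.batch_size, shuffle_rng):
            t_maps = _teacher_maps(teacher, X[b], tags)
            # maps are matched in inference mode (running statistics, no
            # dropout): an exact teacher copy is then a fixed point
            _, _, _, sfeats = student(Tensor(X[b]), training=False)
            s_maps = [losses.attention_map(sfeats[t]) for t in tags]
            loss = losses.attention_transfer_loss(
                s_maps, [t_maps[t] for t in tags])
            _check_finite(float(loss.data), "attention-transfer loss", epoch)
            # maps already matched to numerical precision: stepping on the
            # float residue would only perturb the student (Adam rescales
            # arbitrarily small gradients to full-size steps)
            if float(loss.data) > 1e-9 * len(tags):
                loss.backward()
                opt.step()
                opt.zero_grad()
            total += float(loss.data)
            nb += 1
        rows.append({"epoch": epoch, "at_loss": total / nb})
    return student, pd.DataFrame(rows)


def train_student_kd(student, teacher, windows,
                     w: losses.KDWeights | None = None,
                     cfg: TrainConfig | None = None):
    """Phase 3: fine-tune the (pre-trained) student on
    alpha * L(ground truth) + (1 - alpha) * L(teacher prediction), both
    heads included.  The teacher is frozen (its parameters are never
    touched).  Returns ``(student, metrics)`` logging both components and
    alpha per epoch."""
    w = w or losses.KDWeights()
    cfg = cfg or TrainConfig()
    X, y_resp, y_rr = windows_to_arrays(windows)
    # the student adopts the teacher's rate standardisation, so the raw
    # teacher output is directly usable as the imitation target
    student.rr_norm = {k: np.array(v) for k, v in teacher.rr_norm.items()}
    offset = float(student.rr_norm["offset"])
    scale = float(student.rr_norm["scale"])
    y_rr = (y_rr - offset) / scale
    ss = np.random.SeedSequence(cfg.seed + 2)
    shuffle_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    opt = Adam(student.parameters(), lr=lr_at(1, cfg.dataset_key))
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_at(epoch, cfg.dataset_key)
        total, gt_total, im_total, nb = 0.0, 0.0, 0.0, 0
        for b in _batches(len(X), cfg.batch_size, shuffle_rng):
            t_resp, t_rr, _, _ = teacher(Tensor(X[b]), training=False)
            s_resp, s_rr, _, _ = student(Tensor(X[b]), training=True,
                                         rng=drop_rng)
            gt = (y_resp[b][:, None, :], y_rr[b][:, None])
            loss = losses.kd_loss((s_resp, s_rr), (t_resp.data, t_rr.data),
                                  gt, w)
            _check_finite(float(loss.data), "distillation loss", epoch)
            loss.backward()
            opt.step()
            opt.zero_grad()
            total += float(loss.data)
            gt_total += losses.multitask_loss(s_resp.data, gt[0],
                                              s_rr.data, gt[1])
            im_total += losses.multitask_loss(s_resp.data, t_resp.data,
                                              s_rr.data, t_rr.data)
            nb += 1
        rows.append({"epoch": epoch, "lr": opt.lr, "alpha": w.alpha,
                     "kd_loss": total / nb, "gt_loss": gt_total / nb,
                     "imitation_loss": im_total / nb})
    return student, pd.DataFrame(rows)


def _avg_rr_mae(model, windows) -> float:
    X, _, y_rr = windows_to_arrays(windows)
    out = _net.forward(model, X)
    return _mae(out.rr, y_rr)


def select_student_size(teacher, windows=None, ned_list=(1, 2, 3, 4),
                        cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Candidate-student report: reference (full-width) parameter count per
    encoder-decoder level count, plus — when training windows are given —
    the percentage increase in held-out average-RR MAE over the teacher.

    Error columns are computed at the width of the supplied teacher;
    parameter counts always refer to the full-width reference design.
    """
    ned_list = sorted(ned_list)
    if any(n < 1 or n > 4 for n in ned_list):
        raise ValueError("student ned must lie in 1..4")
    teach_mae = None
    train, test = None, None
    if windows is not None:
        cfg = cfg or TrainConfig()
        from .respsig import train_test_split
        train, test = train_test_split(windows, cfg.split, cfg.split_mode,
                                       cfg.seed)
        teach_mae = _avg_rr_mae(teacher, test)
    rows = []
    for ned in ned_list:
        count = _net.build_student(_net.student_config(ned=ned)).n_parameters()
        row = {"ned": ned, "parameter_count": count,
               "pct_error_increment": np.nan}
        if windows is not None:
            scfg = _net.student_config(
                ned=ned, width_scale=teacher.cfg.width_scale,
                seed=teacher.cfg.seed)
            student = _net.build_student(scfg)
            student, _ = train_teacher(train, cfg, model=student)
            s_mae = _avg_rr_mae(student, test)
            row["pct_error_increment"] = 100.0 * (s_mae - teach_mae) / teach_mae
        rows.append(row)
    return pd.DataFrame(rows)
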