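import numpy as np
import pytest

from respiraflow import distill, losses, net
from respiraflow.distill import (TrainConfig, lr_at, pretrain_student_at,
                                 select_student_size, train_student_kd,
                                 train_teacher)


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,key,expected", [
        (1, "dalia", 1e-2), (20, "dalia", 1e-2), (21, "dalia", 1e-4),
        (100, "dalia", 1e-4), (1, "ir", 1e-2), (20, "ir", 1e-2),
        (21, "ir", 1e-3), (100, "ir", 1e-3),
    ])
    def test_piecewise_values(self, epoch, key, expected):
        assert lr_at(epoch, key) == expected

    def test_unknown_key_warns_and_falls_back(self):
        with pytest.warns(UserWarning):
            assert lr_at(50, "mystery") == lr_at(50, "ir")

    def test_epoch_numbering_starts_at_one(self):
        with pytest.raises(ValueError):
            lr_at(0, "ir")


@pytest.fixture(scope="module")
def train_windows(small_windows):
    return small_windows[:16]


def _tiny_cfg(epochs=2, at_epochs=2, **kw):
    return TrainConfig(epochs=epochs, batch_size=8, dataset_key="ir",
                       at_epochs=at_epochs, seed=0, **kw)


def _tiny_teacher_cfg(seed=0):
    return net.teacher_config(width_scale=0.0625, seed=seed)


class TestTrainTeacher:
    def test_single_batch_single_epoch_smoke(self, train_windows):
        model, metrics = train_teacher(
            train_windows[:8], _tiny_cfg(epochs=1),
            _tiny_teacher_cfg())
        assert len(metrics) == 1
        assert {"epoch", "lr", "train_loss"} <= set(metrics.columns)
        assert np.isfinite(metrics["train_loss"].iloc[0])

    def test_same_seed_reproduces_final_loss(self, train_windows):
        _, m1 = train_teacher(train_windows, _tiny_cfg(), _tiny_teacher_cfg())
        _, m2 = train_teacher(train_windows, _tiny_cfg(), _tiny_teacher_cfg())
        assert m1["train_loss"].iloc[-1] == m2["train_loss"].iloc[-1]

    def test_loss_decreases_over_training(self, train_windows):
        _, metrics = train_teacher(train_windows, _tiny_cfg(epochs=8),
                                   _tiny_teacher_cfg())
        assert metrics["train_loss"].iloc[-1] < metrics["train_loss"].iloc[0]

    def test_rate_standardisation_is_stored(self, train_windows):
        model, _ = train_teacher(train_windows, _tiny_cfg(epochs=1),
                                 _tiny_teacher_cfg())
        y = np.array([w.rr_avg_gt for w in train_windows])
        assert float(model.rr_norm["offset"]) == pytest.approx(y.mean())
        assert float(model.rr_norm["scale"]) == pytest.approx(y.std())


@pytest.fixture(scope="module")
def frozen_teacher(train_windows):
    model, _ = train_teacher(train_windows, _tiny_cfg(epochs=3),
                             _tiny_teacher_cfg(seed=1))
    return model


class TestAttentionTransfer:
    def test_identical_twin_has_zero_initial_at_loss(self, train_windows,
                                                     frozen_teacher):
        """A student that is an exact copy of the teacher already matches
        every attention map, so the first epoch's AT loss is ~0 and the
        phase is a no-op."""
        import copy
        twin = copy.deepcopy(frozen_teacher)
        _, metrics = pretrain_student_at(twin, frozen_teacher, train_windows,
                                         cfg=_tiny_cfg())
        assert metrics["at_loss"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_at_loss_decreases(self, train_windows, frozen_teacher):
        student = net.build_student(net.student_config(width_scale=0.0625,
                                                       seed=5))
        _, metrics = pretrain_student_at(student, frozen_teacher,
                                         train_windows,
                                         cfg=_tiny_cfg(at_epochs=6))
        assert metrics["at_loss"].iloc[-1] < metrics["at_loss"].iloc[0]

    def test_teacher_parameters_unchanged_bitwise(self, train_windows,
                                                  frozen_teacher):
        before = {n: p.data.copy() for n, p in frozen_teacher.parameters()}
        student = net.build_student(net.student_config(width_scale=0.0625,
                                                       seed=6))
        pretrain_student_at(student, frozen_teacher, train_windows,
                            cfg=_tiny_cfg())
        train_student_kd(student, frozen_teacher, train_windows,
                         cfg=_tiny_cfg())
        for n, p in frozen_teacher.parameters():
            assert np.array_equal(before[n], p.data), n

    def test_unshared_at_layer_request_raises(self, train_windows,
                                              frozen_teacher):
        student = net.build_student(net.student_config(width_scale=0.0625))
        with pytest.raises(ValueError):
            pretrain_student_at(student, frozen_teacher, train_windows,
                                losses.KDWeights(at_layers=("enc9",)),
                                _tiny_cfg())


class TestKDFineTune:
    def test_alpha_logged_by_default(self, train_windows, frozen_teacher):
        student = net.build_student(net.student_config(width_scale=0.0625,
                                                       seed=7))
        _, metrics = train_student_kd(student, frozen_teacher, train_windows,
                                      cfg=_tiny_cfg())
        assert (metrics["alpha"] == 0.94).all()
        assert {"kd_loss", "gt_loss", "imitation_loss"} <= set(metrics.columns)

    def test_student_adopts_teacher_rate_norm(self, train_windows,
                                              frozen_teacher):
        student = net.build_student(net.student_config(width_scale=0.0625,
                                                       seed=8))
        train_student_kd(student, frozen_teacher, train_windows,
                         cfg=_tiny_cfg())
        assert float(student.rr_norm["offset"]) == \
            float(frozen_teacher.rr_norm["offset"])


class TestSelectStudentSize:
    def test_reference_counts_without_training(self, frozen_teacher):
        df = select_student_size(frozen_teacher, windows=None,
                                 ned_list=(1, 2, 3, 4))
        assert list(df["ned"]) == [1, 2, 3, 4]
        counts = df["parameter_count"].to_numpy()
        assert np.all(np.diff(counts) >= 0)
        assert df["pct_error_increment"].isna().all()

    def test_invalid_ned_rejected(self, frozen_teacher):
        with pytest.raises(ValueError):
            select_student_size(frozen_teacher, None, ned_list=(0,))
        with pytest.raises(ValueError):
            select_student_size(frozen_teacher, None, ned_list=(5,))
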