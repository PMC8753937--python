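import numpy as np
import pytest

import noisyseg.trainer as trainer_mod
from noisyseg.bank import MemoryBank
from noisyseg.correction import LabelState
from noisyseg.data import GoldAccessError
from noisyseg.model import Adam, UNet, get_weights
from noisyseg.trainer import (
    AUG_MODES,
    ConfigError,
    EpochPlan,
    TrainConfig,
    augment,
    build_plan,
    invert_prediction,
    run,
    sgdr_lr,
    standardize,
    train_epoch,
)

TINY = TrainConfig(total_epochs=6, init_epochs=2, n_cycles=2, epochs_per_cycle=2,
                   warmup_epochs=1, sgdr_start_epoch=0, sgdr_period=2,
                   seed=0, model_width=4, model_depth=2)


class TestConfig:
    def test_defaults_validate(self):
        cfg = TrainConfig().validate()
        assert cfg.sgdr_start_epoch == 40
        assert cfg.sgdr_period == 10

    def test_epoch_budget_mismatch(self):
        with pytest.raises(ConfigError, match="total_epochs"):
            TrainConfig(total_epochs=99).validate()

    def test_warmup_equal_to_cycle_rejected(self):
        with pytest.raises(ConfigError, match="warmup"):
            TrainConfig(warmup_epochs=10).validate()

    def test_period_must_match_cycle_length(self):
        with pytest.raises(ConfigError, match="sgdr_period"):
            TrainConfig(sgdr_period=7).validate()


class TestPlan:
    def test_default_plan_shape(self):
        plan = build_plan(TrainConfig())
        assert len(plan) == 100
        assert plan[50].cycle == 1 and plan[50].phase == "warmup"
        assert all(p.phase == "init" for p in plan[:50])
        corrections = [p.epoch for p in plan if p.correct_labels_at_end]
        assert corrections == [59, 69, 79, 89, 99]

    def test_warmup_then_tml_within_cycle(self):
        plan = build_plan(TrainConfig())
        cycle1 = [p for p in plan if p.cycle == 1]
        assert [p.phase for p in cycle1] == ["warmup"] * 3 + ["tml"] * 7

    def test_labels_never_corrected_during_init_or_mid_cycle(self):
        cfg = TrainConfig().validate()
        for p in build_plan(cfg):
            if p.correct_labels_at_end:
                assert p.phase != "init"
                assert (p.epoch - cfg.init_epochs) % cfg.epochs_per_cycle == cfg.epochs_per_cycle - 1

    def test_init_only_schedule(self):
        plan = build_plan(TrainConfig(total_epochs=50, n_cycles=0))
        assert all(p.phase == "init" for p in plan)
        assert not any(p.correct_labels_at_end for p in plan)


class TestSGDR:
    def test_paper_values(self):
        cfg = TrainConfig()
        assert sgdr_lr(39, cfg) == pytest.approx(7e-3, abs=1e-12)
        assert sgdr_lr(40, cfg) == pytest.approx(7e-3, abs=1e-12)
        assert sgdr_lr(45, cfg) == pytest.approx(3.5e-3, abs=1e-12)

    def test_restarts(self):
        cfg = TrainConfig()
        assert sgdr_lr(50, cfg) == pytest.approx(7e-3, abs=1e-12)
        assert sgdr_lr(49, cfg) < sgdr_lr(50, cfg)


class TestAugment:
    @pytest.mark.parametrize("mode", AUG_MODES)
    def test_involution(self, mode, rng):
        x = rng.random((6, 8))
        np.testing.assert_array_equal(invert_prediction(augment(x, mode), mode), x)

    def test_none_is_identity(self, rng):
        x = rng.random((5, 5))
        np.testing.assert_array_equal(augment(x, "none"), x)

    def test_hvflip_commutes(self, rng):
        x = rng.random((6, 6))
        np.testing.assert_array_equal(
            augment(augment(x, "hflip"), "vflip"), augment(x, "hvflip"))
        np.testing.assert_array_equal(
            augment(augment(x, "vflip"), "hflip"), augment(x, "hvflip"))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            augment(np.zeros((2, 2)), "rot90")


def _setup_epoch(records, cfg):
    model = UNet(1, width=cfg.model_width, depth=cfg.model_depth, seed=cfg.seed)
    opt = Adam(model.parameters(), cfg.base_lr)
    bank = MemoryBank()
    states = {r.image_id: LabelState(initial=r.noisy) for r in records}
    return model, opt, bank, states


class TestTrainEpoch:
    def test_bank_updates_per_warmup_epoch(self, tiny_records):
        cfg = TINY.validate()
        model, opt, bank, states = _setup_epoch(tiny_records, cfg)
        rec = EpochPlan(2, "warmup", 1, 7e-3, False)
        train_epoch(model, opt, tiny_records, rec, bank, states, cfg,
                    np.random.default_rng(0))
        for r in tiny_records:
            assert bank.n_updates(r.image_id) == 4

    def test_init_phase_does_not_touch_bank(self, tiny_records):
        cfg = TINY.validate()
        model, opt, bank, states = _setup_epoch(tiny_records, cfg)
        rec = EpochPlan(0, "init", 0, 7e-3, False)
        train_epoch(model, opt, tiny_records, rec, bank, states, cfg,
                    np.random.default_rng(0))
        assert all(bank.n_updates(r.image_id) == 0 for r in tiny_records)

    def test_frozen_weights_record_identical_banks(self, tiny_records):
        cfg = TINY.validate()
        model, opt, bank, states = _setup_epoch(tiny_records, cfg)
        rec = EpochPlan(2, "warmup", 1, 0.0, False)  # lr=0 freezes weights
        train_epoch(model, opt, tiny_records, rec, bank, states, cfg,
                    np.random.default_rng(0))
        first = {r.image_id: (bank.get_best(r.image_id), bank.get_worst(r.image_id))
                 for r in tiny_records}
        train_epoch(model, opt, tiny_records, rec, bank, states, cfg,
                    np.random.default_rng(1))
        for r in tiny_records:
            np.testing.assert_array_equal(bank.get_best(r.image_id), first[r.image_id][0])
            np.testing.assert_array_equal(bank.get_worst(r.image_id), first[r.image_id][1])

    def test_gradient_step_decreases_loss(self, tiny_records):
        cfg = TrainConfig(total_epochs=6, init_epochs=2, n_cycles=2, epochs_per_cycle=2,
                          warmup_epochs=1, sgdr_start_epoch=0, sgdr_period=2,
                          base_lr=1e-4, seed=0, model_width=4, model_depth=2).validate()
        records = tiny_records[:1]
        model, opt, bank, states = _setup_epoch(records, cfg)
        rec = EpochPlan(0, "init", 0, 1e-4, False)
        losses = [train_epoch(model, opt, records, rec, bank, states, cfg,
                              np.random.default_rng(0)) for _ in range(2)]
        assert losses[1] < losses[0]

    def test_tml_with_empty_bank_falls_back_to_warmup(self, tiny_records):
        cfg = TINY.validate()
        model, opt, bank, states = _setup_epoch(tiny_records, cfg)
        rec = EpochPlan(3, "tml", 1, 7e-3, False)
        loss = train_epoch(model, opt, tiny_records, rec, bank, states, cfg,
                           np.random.default_rng(0), use_tml=True)
        assert np.isfinite(loss)


class TestRun:
    def test_seeded_determinism(self, tiny_records):
        a = run(TINY, tiny_records)
        b = run(TINY, tiny_records)
        assert a.report.to_dict() == b.report.to_dict()
        for wa, wb in zip(get_weights(a.model), get_weights(b.model)):
            np.testing.assert_array_equal(wa, wb)

    def test_init_only_is_plain_supervised(self, tiny_records):
        cfg = TrainConfig(total_epochs=2, init_epochs=2, n_cycles=0, epochs_per_cycle=2,
                          warmup_epochs=1, sgdr_start_epoch=0, sgdr_period=2,
                          seed=0, model_width=4, model_depth=2)
        res = run(cfg, tiny_records)
        # no corrections: labels still the initial masks, only baseline logged
        assert [c["cycle"] for c in res.report.cycles] == [0]
        for r in tiny_records:
            np.testing.assert_array_equal(res.label_states[r.image_id].current, r.noisy)

    def test_correction_count_and_phases(self, tiny_records):
        res = run(TINY, tiny_records)
        assert [c["cycle"] for c in res.report.cycles] == [0, 1, 2]
        phases = {e["phase"] for e in res.report.epochs}
        assert phases == {"init", "warmup", "tml"}

    def test_final_labels_left_untrained(self, tiny_records):
        """The last correction produces an export-only label state."""
        res = run(TINY, tiny_records)
        for r in tiny_records:
            assert res.label_states[r.image_id].cycle_index == TINY.n_cycles + 1

    def test_gold_never_read_during_training(self, tiny_records, monkeypatch):
        orig = trainer_mod.train_epoch

        def probing(model, opt, records, plan_rec, bank, states, cfg, rng, **kw):
            with pytest.raises(GoldAccessError):
                records[0].gold
            return orig(model, opt, records, plan_rec, bank, states, cfg, rng, **kw)

        monkeypatch.setattr(trainer_mod, "train_epoch", probing)
        run(TINY, tiny_records)
        # guard released afterwards
        assert tiny_records[0].gold is not None

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run(TINY, [])

    def test_unknown_variant_rejected(self, tiny_records):
        with pytest.raises(ValueError, match="variant"):
            run(TINY, tiny_records, variant="bogus")

    def test_test_records_logged(self, tiny_records):
        res = run(TINY, tiny_records[:1], test_records=tiny_records[1:])
        assert all(e["test_loss"] is not None for e in res.report.epochs)


class TestStandardize:
    def test_zero_mean_unit_std(self, rng):
        x = standardize(rng.random((16, 16)))
        assert abs(x.mean()) < 1e-12
        assert abs(x.std() - 1.0) < 1e-12
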