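import numpy as np
import pytest

from mosaicx.event_caller import (
    CallerParams,
    MosaicCall,
    SegmentRejected,
    call_events,
    classify_copy_state,
    classify_location,
    estimate_mosaic_fraction,
    fit_baf_mixture,
    screen_constitutional,
)
from mosaicx.probe_model import ClusterBatch, MosaicXWarning, ProbeMap
from mosaicx.synthetic_data import EventSpec, delta_b_for, simulate_sample


def hg18ish_map(n=200, length=154_913_754):
    pos = np.linspace(1000, length - 1000, n).astype(np.int64)
    return ProbeMap(
        probe_ids=tuple(f"p{i}" for i in range(n)),
        positions=pos,
        chromosome="X",
        chrom_length=length,
        centromere=(58_500_000, 61_700_000),
    )


def allele_count_oracle(f, state, n_cells=200_000, seed=0):
    """Brute-force mixture of cells: returns the het-band BAF deviation.

    Normal cells carry alleles A+B; altered cells carry the state's allele
    complement for the branch in which the B-homolog is affected.
    """
    rng = np.random.default_rng(seed)
    altered = rng.random(n_cells) < f
    n_alt = altered.sum()
    n_norm = n_cells - n_alt
    if state == "loss":          # altered cells lost the B homolog
        b, total = n_norm, 2 * n_norm + n_alt
    elif state == "gain":        # altered cells gained an extra A homolog
        b, total = n_norm + n_alt, 2 * n_norm + 3 * n_alt
    else:                        # copy-neutral: B replaced by A
        b, total = n_norm, 2 * n_cells
    return abs(b / total - 0.5)


class TestFitBafMixture:
    def test_mosaic_split_detected_k4(self, rng):
        hom = np.clip(np.concatenate([
            rng.normal(0.01, 0.03, 175), rng.normal(0.99, 0.03, 175)
        ]), 0, 1)
        het = np.concatenate([
            rng.normal(0.35, 0.03, 75), rng.normal(0.65, 0.03, 75)
        ])
        fit = fit_baf_mixture(np.concatenate([hom, het]), seed=0)
        assert fit.k == 4
        assert fit.delta_b_hat == pytest.approx(0.15, abs=0.01)

    def test_normal_het_band_k3(self, rng):
        hom = np.clip(np.concatenate([
            rng.normal(0.0, 0.03, 175), rng.normal(1.0, 0.03, 175)
        ]), 0, 1)
        het = rng.normal(0.5, 0.03, 150)
        fit = fit_baf_mixture(np.concatenate([hom, het]), seed=0)
        assert fit.k == 3
        assert fit.delta_b_hat == 0.0

    def test_complete_loh_k2(self, rng):
        x = np.clip(np.concatenate([
            rng.normal(0.0, 0.02, 250), rng.normal(1.0, 0.02, 250)
        ]), 0, 1)
        fit = fit_baf_mixture(x, seed=0)
        assert fit.k == 2

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="50"):
            fit_baf_mixture(np.full(20, 0.5))

    def test_invariants(self, rng):
        x = np.clip(rng.normal(0.5, 0.1, 300), 0, 1)
        fit = fit_baf_mixture(x, seed=1)
        assert sum(fit.weights) == pytest.approx(1.0)
        assert list(fit.means) == sorted(fit.means)


class TestClassifyCopyState:
    @pytest.mark.parametrize(
        "delta_lrr,whole,expected",
        [
            (-0.20, True, "loss"),
            (+0.02, False, "copy-neutral"),
            (+0.02, True, "gain"),
            (-0.02, True, "loss"),
            (-0.06, False, "loss"),
            (+0.06, False, "gain"),
            (0.01, True, "copy-neutral"),   # boundary strict
            (0.05, False, "copy-neutral"),  # boundary strict
            (0.0, True, "copy-neutral"),
        ],
    )
    def test_thresholds(self, delta_lrr, whole, expected):
        assert classify_copy_state(delta_lrr, whole) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_copy_state(np.nan, True)


class TestEstimateMosaicFraction:
    def test_copy_neutral(self):
        assert estimate_mosaic_fraction(0.15, "copy-neutral") == pytest.approx(0.30)

    def test_loss_allele_oracle_value(self):
        # mixing 40% one-X cells with 60% diploid gives het BAF 0.375/0.625
        assert estimate_mosaic_fraction(0.125, "loss") == pytest.approx(0.40)

    def test_gain_trisomic_limit(self):
        assert estimate_mosaic_fraction(1 / 6, "gain") == pytest.approx(1.0)

    def test_zero(self):
        for state in ("loss", "gain", "copy-neutral"):
            assert estimate_mosaic_fraction(0.0, state) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            estimate_mosaic_fraction(-0.01, "loss")

    def test_gain_above_limit_warns_and_caps(self):
        with pytest.warns(MosaicXWarning, match="capped"):
            assert estimate_mosaic_fraction(0.2, "gain") == 1.0

    @pytest.mark.parametrize("state", ["loss", "gain", "copy-neutral"])
    def test_strictly_increasing(self, state):
        grid = np.linspace(0, 0.16, 30)
        vals = [estimate_mosaic_fraction(d, state) for d in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("state", ["loss", "gain", "copy-neutral"])
    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5, 0.8])
    def test_inverse_consistency_with_cell_mixture(self, state, f):
        db = allele_count_oracle(f, state, seed=hash((state, f)) % 2**32)
        # Monte-Carlo error of the simulated deviation at n=200k cells
        assert estimate_mosaic_fraction(db, state) == pytest.approx(f, abs=0.02)

    @pytest.mark.parametrize("state", ["loss", "gain", "copy-neutral"])
    @pytest.mark.parametrize("f", [0.2, 0.6])
    def test_closed_form_matches_forward_model(self, state, f):
        assert estimate_mosaic_fraction(delta_b_for(state, f), state) == \
            pytest.approx(f, rel=1e-12)


class TestClassifyLocation:
    def test_whole(self):
        pm = hg18ish_map()
        assert classify_location(500, pm.chrom_length, pm) == "whole"

    def test_telomeric_p(self):
        pm = hg18ish_map()
        assert classify_location(500, 30_000_000, pm) == "telomeric p"

    def test_spans_centromere(self):
        pm = hg18ish_map()
        assert classify_location(40_000_000, 80_000_000, pm) == "spans centromere"

    def test_interstitial(self):
        pm = hg18ish_map()
        assert classify_location(70_000_000, 90_000_000, pm) == "interstitial"

    def test_telomeric_q(self):
        pm = hg18ish_map()
        assert classify_location(100_000_000, 154_900_000, pm) == "telomeric q"

    def test_out_of_bounds(self):
        pm = hg18ish_map()
        with pytest.raises(ValueError, match="outside"):
            classify_location(100, 200_000_000, pm)

    def test_exhaustive_partition(self):
        # exactly one category for every valid interval
        pm = hg18ish_map()
        rng = np.random.default_rng(0)
        starts = rng.integers(0, pm.chrom_length - 1, 10_000)
        ends = rng.integers(starts + 1, pm.chrom_length + 1)
        for s, e in zip(starts, ends):
            loc = classify_location(int(s), int(e), pm)
            assert loc in (
                "interstitial", "spans centromere", "telomeric p",
                "telomeric q", "whole",
            )


class TestScreenConstitutional:
    def call(self, state, location, fraction):
        return MosaicCall(
            sample_id="S", start_bp=0, end_bp=154_913_754, n_probes=100,
            state=state, location=location, delta_b=0.4, delta_lrr=-1.0,
            fraction=fraction, whole_flag=location == "whole",
        )

    def test_xo_flagged(self):
        retained, flagged = screen_constitutional([self.call("loss", "whole", 0.98)])
        assert retained == []
        assert flagged[0].flags == ("XO",)

    def test_trisomy_flagged(self):
        _, flagged = screen_constitutional([self.call("gain", "whole", 0.97)])
        assert flagged[0].flags == ("trisomy_X",)

    def test_mosaic_whole_loss_retained(self):
        retained, flagged = screen_constitutional([self.call("loss", "whole", 0.40)])
        assert len(retained) == 1 and not flagged

    def test_high_fraction_cnloh_retained(self):
        retained, flagged = screen_constitutional(
            [self.call("copy-neutral", "interstitial", 0.97)]
        )
        assert len(retained) == 1 and not flagged


class TestCallEvents:
    def test_whole_chromosome_loss(self, sim_config, probe_map, batch0,
                                   caller_params):
        ev = EventSpec("loss", "Xi", 0, sim_config.chrom_length, 0.4)
        s = simulate_sample([ev], probe_map, batch0, sim_config,
                            seed_index=501, sample_id="S1")
        calls, constitutional = call_events(s, probe_map, batch0, caller_params)
        assert len(calls) == 1 and not constitutional
        c = calls[0]
        assert c.state == "loss"
        assert c.location == "whole"
        assert c.fraction == pytest.approx(0.4, abs=0.05)

    def test_no_events_empty(self, sim_config, probe_map, batch0, caller_params):
        s = simulate_sample([], probe_map, batch0, sim_config,
                            seed_index=502, sample_id="S2")
        calls, constitutional = call_events(s, probe_map, batch0, caller_params)
        assert calls == [] and constitutional == []

    def test_two_interstitial_cnloh(self, batch0, caller_params):
        # +/-0.5 Mb boundary accuracy needs array-like probe density
        from mosaicx.synthetic_data import SimulationConfig, make_probe_map

        cfg = SimulationConfig(seed=11, n_probes=6000)
        dense_map = make_probe_map(cfg.n_probes, cfg)
        evs = [
            EventSpec("copy-neutral", "Xi", 25_000_000, 30_000_000, 0.3),
            EventSpec("copy-neutral", "Xa", 47_000_000, 52_000_000, 0.3),
        ]
        s = simulate_sample(evs, dense_map, batch0, cfg,
                            seed_index=503, sample_id="S3")
        calls, _ = call_events(s, dense_map, batch0, caller_params)
        assert len(calls) == 2
        for call, ev in zip(calls, evs):
            assert call.state == "copy-neutral"
            assert call.start_bp == pytest.approx(ev.start_bp, abs=500_000)
            assert call.end_bp == pytest.approx(ev.end_bp, abs=500_000)

    def test_constitutional_xo_detected(self, sim_config, probe_map, batch0,
                                        caller_params):
        ev = EventSpec("loss", "Xi", 0, sim_config.chrom_length, 1.0)
        s = simulate_sample([ev], probe_map, batch0, sim_config,
                            seed_index=504, sample_id="S4")
        calls, constitutional = call_events(s, probe_map, batch0, caller_params)
        assert calls == []
        assert len(constitutional) == 1
        assert "XO" in constitutional[0].flags
        assert constitutional[0].fraction >= 0.95

    def test_no_call_below_2mb(self, sim_config, probe_map, batch0,
                               caller_params):
        evs = [EventSpec("copy-neutral", "Xi", 40_000_000, 60_000_000, 0.5)]
        s = simulate_sample(evs, probe_map, batch0, sim_config,
                            seed_index=505, sample_id="S5")
        calls, constitutional = call_events(s, probe_map, batch0, caller_params)
        for c in calls + constitutional:
            assert c.end_bp - c.start_bp >= 2_000_000
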