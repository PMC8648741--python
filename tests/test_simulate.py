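"""The synthetic cohort generator: determinism, density law, survival."""

import numpy as np
import pytest

from svhot.core import count_breakpoints_in_track, total_breakpoints
from svhot.simulate import (
    BreakpointSampler,
    GeneSpec,
    SimulationConfig,
    TrackSpec,
    assign_groups,
    default_config,
    simulate_cohort_breakpoints,
    simulate_genome_and_tracks,
    simulate_index_cohort,
    simulate_survival,
)
from svhot.survival import km_median


def small_config(**kw):
    base = dict(
        seed=5,
        chromosome_lengths={"chr1": 1_000_000, "chr2": 1_000_000},
        track_specs={"A": TrackSpec(50, 1000.0), "B": TrackSpec(30, 500.0)},
        enrichment={"A": 1.0, "B": 1.0},
        n_samples=6,
        gene_spec=GeneSpec(n_genes=20, length_mean=5000.0),
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenomeAndTracks:
    def test_zero_elements_gives_empty_track(self):
        cfg = small_config(track_specs={"A": TrackSpec(0)})
        _, tracks, _ = simulate_genome_and_tracks(cfg)
        assert len(tracks["A"]) == 0

    def test_same_seed_identical_outputs(self):
        cfg = small_config()
        g1, t1, gm1 = simulate_genome_and_tracks(cfg)
        g2, t2, gm2 = simulate_genome_and_tracks(cfg)
        for cls in t1:
            assert list(t1[cls].starts) == list(t2[cls].starts)
        assert list(gm1.track.starts) == list(gm2.track.starts)

    def test_elements_disjoint_and_length_matches_bitmap(self):
        cfg = small_config(
            chromosome_lengths={"chr1": 1_000_000},
            track_specs={"A": TrackSpec(200, 800.0, length_sd=300.0)},
        )
        _, tracks, _ = simulate_genome_and_tracks(cfg)
        t = tracks["A"]
        bitmap = np.zeros(1_000_000, dtype=bool)
        total = 0
        for s, e in zip(t.starts, t.ends):
            bitmap[s:e] = True
            total += e - s
        # placement never overlaps, so merged length == summed length
        assert int(bitmap.sum()) == total == t.cumulative_length()

    def test_track_mass_exceeding_genome_rejected(self):
        cfg = small_config(
            chromosome_lengths={"chr1": 10_000},
            track_specs={"A": TrackSpec(30, 1000.0)},
        )
        with pytest.raises(ValueError, match="mass"):
            simulate_genome_and_tracks(cfg)


class TestBreakpointCohort:
    def test_unknown_enrichment_class_rejected(self):
        cfg = small_config(enrichment={"A": 1.0, "Z": 2.0})
        genome, tracks, _ = simulate_genome_and_tracks(small_config())
        with pytest.raises(ValueError, match="unknown"):
            simulate_cohort_breakpoints(cfg, genome, tracks)

    def test_factor_zero_keeps_territory_empty(self):
        cfg = small_config(enrichment={"A": 0.0, "B": 1.0}, n_samples=4)
        genome, tracks, _ = simulate_genome_and_tracks(cfg)
        catalogs = simulate_cohort_breakpoints(cfg, genome, tracks)
        assert count_breakpoints_in_track(catalogs, tracks["A"], genome) == 0

    def test_neutral_factors_match_binomial_bands(self):
        # under factor 1 everywhere the per-track count is Binomial(TBPc, Li/L)
        cfg = small_config(n_samples=60, enrichment={})
        genome, tracks, _ = simulate_genome_and_tracks(cfg)
        catalogs = simulate_cohort_breakpoints(cfg, genome, tracks)
        li = tracks["A"].cumulative_length()
        frac = li / genome.readable_size
        inside_band = 0
        for cat in catalogs:
            n = cat.tbpc
            k = count_breakpoints_in_track(cat, tracks["A"], genome)
            sd = np.sqrt(n * frac * (1 - frac))
            inside_band += abs(k - n * frac) <= 3 * sd + 1
        assert inside_band >= 0.95 * len(catalogs)

    def test_enrichment_factor_shifts_mean_count(self):
        factor = 10.0
        cfg = small_config(
            chromosome_lengths={"chr1": 10_000_000},
            track_specs={"A": TrackSpec(50, 10_000.0)},  # 0.5 Mb territory
            enrichment={"A": factor},
            n_samples=40,
        )
        genome, tracks, _ = simulate_genome_and_tracks(cfg)
        catalogs = simulate_cohort_breakpoints(cfg, genome, tracks)
        li = tracks["A"].cumulative_length()
        L = genome.readable_size
        mass = factor * li + (L - li)
        expected_frac = factor * li / mass
        counts = np.array(
            [count_breakpoints_in_track(c, tracks["A"], genome) for c in catalogs]
        )
        tbpc = np.array([c.tbpc for c in catalogs])
        observed = counts.sum() / tbpc.sum()
        assert observed == pytest.approx(expected_frac, rel=0.15)

    def test_sv_pairing_and_intra_fraction(self):
        cfg = small_config(n_samples=30, intra_sv_fraction=0.7)
        genome, tracks, _ = simulate_genome_and_tracks(cfg)
        catalogs = simulate_cohort_breakpoints(cfg, genome, tracks)
        intra = sum(c.n_bpsv_intra for c in catalogs)
        total = total_breakpoints(catalogs)
        assert intra / total == pytest.approx(0.7, abs=0.06)

    def test_tbpc_within_configured_bounds(self):
        cfg = small_config(n_samples=50)
        genome, tracks, _ = simulate_genome_and_tracks(cfg)
        catalogs = simulate_cohort_breakpoints(cfg, genome, tracks)
        lo, hi = cfg.tbpc_bounds
        for c in catalogs:
            assert lo <= c.tbpc <= hi + 1
            assert c.tbpc % 2 == 0


class TestSampler:
    def test_restrict_and_exclude_chromosome(self, rng):
        cfg = small_config()
        genome, tracks, _ = simulate_genome_and_tracks(cfg)
        sampler = BreakpointSampler(genome, tracks, {})
        ci, _ = sampler.sample(rng, 50, restrict_chrom="chr2")
        assert all(sampler.chrom_names[c] == "chr2" for c in ci)
        ci, _ = sampler.sample(rng, 50, exclude_chrom="chr2")
        assert all(sampler.chrom_names[c] != "chr2" for c in ci)


class TestSurvival:
    def test_medium_group_has_lowest_km_median(self):
        cfg = SimulationConfig(seed=11, n_samples=300)
        values, recs = simulate_index_cohort(cfg)
        groups = assign_groups(values, cfg.true_thresholds)
        medians = {}
        for g in ("Low", "Medium", "High"):
            member = [r for r in recs if groups[r.sample_id] == g]
            medians[g] = km_median(
                [r.time for r in member], [r.event for r in member]
            )
        assert medians["Medium"] < min(medians["Low"], medians["High"])

    def test_full_censoring_gives_no_events(self):
        cfg = small_config(censoring_rate=1.0)
        recs = simulate_survival({f"s{i}": "Low" for i in range(20)}, cfg)
        assert all(r.event == 0 for r in recs)

    def test_same_seed_identical_records(self):
        cfg = small_config()
        groups = {f"s{i}": "Medium" for i in range(10)}
        r1 = simulate_survival(groups, cfg)
        r2 = simulate_survival(groups, cfg)
        assert r1 == r2

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="hazard"):
            simulate_survival({"a": "Weird"}, small_config())

    def test_censoring_rate_near_target(self):
        # huge follow-up cap isolates the random-censoring rate parameter
        cfg = SimulationConfig(seed=3, n_samples=400, censoring_rate=0.2,
                               max_follow_years=1e6)
        _, recs = simulate_index_cohort(cfg)
        censored = np.mean([1 - r.event for r in recs])
        assert censored == pytest.approx(0.2, abs=0.07)


def test_default_config_covers_all_classes():
    cfg = default_config()
    from svhot.indexes import RACIN_CLASSES, TRACE_CLASSES

    present = set(cfg.track_specs)
    assert set(TRACE_CLASSES) <= present and set(RACIN_CLASSES) <= present


def test_config_roundtrip_through_dict():
    cfg = small_config()
    again = SimulationConfig.from_dict(cfg.to_dict())
    assert again == cfg
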