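import numpy as np
import pandas as pd
import pytest

from larvanet import (
    ReleaseSpec,
    advect,
    aggregate_species,
    build_release,
    category_weights,
    connection_matrix,
    detect_arrivals,
    dispersal_flux,
    recruitment_fractions,
)
from larvanet.connectivity import ARRIVAL_COLUMNS, connectivity_result, edge_list
from larvanet.errors import ConsistencyError
from larvanet.lagrangian import ALIVE, DEAD_MORTALITY, ParticleEnsemble
from larvanet.registry import SpeciesParams

from _oracles import arrivals_brute, connectivity_brute


def hand_ensemble(lons, lats, status=None, origins=None):
    """Build a ParticleEnsemble directly from per-particle sample paths."""
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    n, nt = lons.shape
    status = (np.zeros((n, nt), np.int8) if status is None
              else np.asarray(status, np.int8))
    origins = np.asarray(origins if origins is not None else ["A"] * n)
    times = (np.datetime64("2016-06-01", "ns")
             + np.arange(nt) * np.timedelta64(6 * 3600 * 10 ** 9, "ns"))
    return ParticleEnsemble(
        species_name="hand", origin_mpa=origins, lon=lons, lat=lats,
        status=status, stranded=np.zeros((n, nt), bool), record_times=times,
        age_days=np.zeros(n), rng_seed=0, depth_m=5.0,
        released_per_origin={m: int((origins == m).sum())
                             for m in np.unique(origins)})


class TestDetectArrivals:
    def test_zero_flow_arrivals_are_origin_at_t0(self, species_table,
                                                 registry, still_field):
        sp = next(s for s in species_table if s.name == "Acropora solitaryensis")
        rel = build_release(sp, registry, particles_per_point=10)
        ens = advect(rel, still_field, mortality_rate_per_day=0.0, seed=0)
        arr = detect_arrivals(ens, registry)
        assert set(arr.columns) == set(ARRIVAL_COLUMNS)
        assert len(arr) == ens.n_particles
        assert (arr["origin_mpa"] == arr["visited_mpa"]).all()
        assert (arr["record_index"] == 0).all()

    def test_reentry_keeps_first_entry_only(self, registry):
        """A path entering, leaving, and re-entering an MPA yields one record
        with the earlier time (brute-force scan of the toy trajectory)."""
        site = registry[0]
        lon_c, lat_c = site.center
        path_lon = [lon_c, lon_c + 5.0, lon_c]  # in -> far away -> back in
        path_lat = [lat_c, lat_c, lat_c]
        ens = hand_ensemble([path_lon], [path_lat],
                            origins=[site.mpa_id])
        arr = detect_arrivals(ens, registry)
        hits = arr[arr["visited_mpa"] == site.mpa_id]
        assert len(hits) == 1
        assert hits["record_index"].iloc[0] == 0
        brute = arrivals_brute(ens, registry)
        assert sorted((r[0], r[2], r[3]) for r in brute) == sorted(
            zip(arr["particle"], arr["visited_mpa"], arr["record_index"]))

    def test_entries_after_death_not_recorded(self, registry):
        site = registry[0]
        lon_c, lat_c = site.center
        status = [[DEAD_MORTALITY, DEAD_MORTALITY]]
        ens = hand_ensemble([[lon_c, lon_c]], [[lat_c, lat_c]],
                            status=status, origins=[site.mpa_id])
        assert detect_arrivals(ens, registry).empty

    def test_end_of_pld_mode_uses_final_sample_only(self, registry):
        a, b = registry[0], registry[1]
        # visits A mid-run but ends inside B
        lons = [[a.center[0], a.center[0], b.center[0]]]
        lats = [[a.center[1], a.center[1], b.center[1]]]
        ens = hand_ensemble(lons, lats, origins=[a.mpa_id])
        arr = detect_arrivals(ens, registry, mode="end_of_pld")
        assert arr["visited_mpa"].tolist() == [b.mpa_id]

    def test_unknown_origin_raises(self, registry):
        ens = hand_ensemble([[0.0]], [[0.0]], origins=["NOWHERE"])
        with pytest.raises(ConsistencyError):
            detect_arrivals(ens, registry)


class TestBruteForceEquivalence:
    def test_toy_run_recount_is_exact(self, species_table, registry,
                                      default_field):
        """On a <=100-particle run, an independent scalar re-scan of the raw
        trajectories reproduces arrivals, c, d, selfr, subr exactly."""
        sp = next(s for s in species_table if s.name == "Anguilla japonica")
        rel = build_release(sp, registry, particles_per_point=4)  # 84 particles
        ens = advect(rel, default_field, mortality_rate_per_day=0.15, seed=21)
        arr = detect_arrivals(ens, registry)
        mpa_ids = [s.mpa_id for s in registry]
        res = connectivity_result(sp.name, arr, ens.released_per_origin,
                                  mpa_ids)
        brute = arrivals_brute(ens, registry)
        assert sorted((r[0], r[2], r[3]) for r in brute) == sorted(
            zip(arr["particle"], arr["visited_mpa"], arr["record_index"]))
        c_b, r_b, d_b, selfr_b, subr_b = connectivity_brute(
            brute, ens.released_per_origin, mpa_ids)
        assert np.array_equal(res.c_matrix.to_numpy(), c_b)
        assert np.array_equal(res.d_flux["r"].to_numpy(), r_b)
        assert np.array_equal(res.d_flux["d"].to_numpy(), d_b)
        assert np.array_equal(res.recruitment["selfr"].to_numpy(), selfr_b)
        assert np.array_equal(res.recruitment["subr"].to_numpy(), subr_b)


class TestDispersalFlux:
    def test_direct_normalization(self):
        arr = pd.DataFrame({
            "particle": range(100),
            "origin_mpa": ["A"] * 100,
            "visited_mpa": ["A"] * 10 + ["B"] * 30 + ["C"] * 60,
            "record_index": 0, "time": pd.NaT, "alive_at_entry": True})
        flux = dispersal_flux(arr, 1000, ["A", "B", "C"])
        assert flux["d"].tolist() == [0.1, 0.3, 0.6]
        assert flux["d_abs"].tolist() == [0.01, 0.03, 0.06]

    def test_concentration_case(self):
        arr = pd.DataFrame({"particle": [0, 1], "origin_mpa": "A",
                            "visited_mpa": "B", "record_index": 0,
                            "time": pd.NaT, "alive_at_entry": True})
        flux = dispersal_flux(arr, 10, ["A", "B"])
        assert flux["d"].tolist() == [0.0, 1.0]

    def test_no_arrivals_warns_with_zeros(self):
        flux = dispersal_flux(pd.DataFrame(columns=ARRIVAL_COLUMNS), 10,
                              ["A", "B"])
        assert flux.attrs["no_arrivals"]
        assert (flux["d"] == 0).all()

    def test_zero_released_raises(self):
        with pytest.raises(ValueError):
            dispersal_flux(pd.DataFrame(columns=ARRIVAL_COLUMNS), 0, ["A"])

    def test_flux_sums_to_one(self, species_table, registry, default_field):
        sp = next(s for s in species_table if s.name == "Penaeus japonicus")
        rel = build_release(sp, registry, particles_per_point=5)
        ens = advect(rel, default_field, seed=2)
        arr = detect_arrivals(ens, registry)
        flux = dispersal_flux(arr, rel.total_particles,
                              [s.mpa_id for s in registry])
        assert flux["d"].sum() == pytest.approx(1.0, abs=1e-12)


class TestConnectionMatrix:
    def test_proportion_arithmetic(self):
        arr = pd.DataFrame({
            "particle": range(20), "origin_mpa": ["I"] * 20,
            "visited_mpa": ["J"] * 20, "record_index": 1, "time": pd.NaT,
            "alive_at_entry": True})
        c = connection_matrix(arr, {"I": 1000}, ["I", "J"])
        assert c.loc["I", "J"] == 0.02

    def test_zero_flow_identity_on_occupied_mpas(self, species_table,
                                                 registry, still_field):
        """No transport and no mortality: every particle stays home, so c is
        the identity restricted to occupied MPAs and selfr = 1 there."""
        sp = next(s for s in species_table if s.name == "Acropora solitaryensis")
        rel = build_release(sp, registry, particles_per_point=10)
        ens = advect(rel, still_field, mortality_rate_per_day=0.0, seed=0)
        arr = detect_arrivals(ens, registry)
        mpa_ids = [s.mpa_id for s in registry]
        c = connection_matrix(arr, ens.released_per_origin, mpa_ids)
        expected = np.zeros((21, 21))
        for m in sp.occupied_mpas:
            k = mpa_ids.index(m)
            expected[k, k] = 1.0
        assert np.array_equal(c.to_numpy(), expected)
        rec = recruitment_fractions(c)
        for m in sp.occupied_mpas:
            assert rec.loc[m, "selfr"] == 1.0
            assert rec.loc[m, "subr"] == 0.0

    def test_unknown_origin_raises(self):
        arr = pd.DataFrame({"particle": [0], "origin_mpa": ["X"],
                            "visited_mpa": ["Y"], "record_index": 0,
                            "time": pd.NaT, "alive_at_entry": True})
        with pytest.raises(ConsistencyError):
            connection_matrix(arr, {"Y": 10}, ["X", "Y"])

    def test_mortality_never_increases_transport(self, species_table,
                                                 registry, default_field):
        """Raising mortality cannot raise off-diagonal c(i,j) in expectation
        (averaged over seeds)."""
        sp = next(s for s in species_table if s.name == "Anguilla japonica")
        rel = build_release(sp, registry, particles_per_point=5)
        mpa_ids = [s.mpa_id for s in registry]

        def mean_offdiag(rate):
            vals = []
            for seed in range(4):
                ens = advect(rel, default_field, mortality_rate_per_day=rate,
                             seed=seed)
                arr = detect_arrivals(ens, registry)
                c = connection_matrix(arr, ens.released_per_origin, mpa_ids)
                m = c.to_numpy()
                vals.append(m.sum() - np.trace(m))
            return np.mean(vals)

        assert mean_offdiag(0.6) <= mean_offdiag(0.0)


class TestRecruitmentFractions:
    def test_pure_self_recruitment(self):
        c = pd.DataFrame(np.diag([0.05, 0.0]), index=["A", "B"],
                         columns=["A", "B"])
        rec = recruitment_fractions(c)
        assert rec.loc["A", "selfr"] == 1.0 and rec.loc["A", "subr"] == 0.0
        assert not rec.loc["B", "defined"]
        assert rec.loc["B", "selfr"] == 0.0  # flagged, not NaN

    def test_pure_export(self):
        c = pd.DataFrame([[0.0, 0.01], [0.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        rec = recruitment_fractions(c)
        assert rec.loc["A", "selfr"] == 0.0 and rec.loc["A", "subr"] == 1.0

    def test_printed_equation_row_normalization(self):
        c = pd.DataFrame([[0.02, 0.01, 0.01], [0, 0, 0], [0, 0, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        rec = recruitment_fractions(c)
        assert rec.loc["A", "selfr"] == 0.5 and rec.loc["A", "subr"] == 0.5

    def test_incoming_orientation_uses_columns(self):
        c = pd.DataFrame([[0.1, 0.1], [0.3, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        rec = recruitment_fractions(c, orientation="incoming")
        assert rec.attrs["orientation"] == "incoming"
        assert rec.loc["A", "selfr"] == pytest.approx(0.25)  # 0.1/(0.1+0.3)
        assert rec.loc["A", "subr"] == pytest.approx(0.75)

    def test_selfr_plus_subr_is_one_where_defined(self, species_table,
                                                  registry, default_field):
        sp = next(s for s in species_table if s.name == "Epinephelus akaara")
        rel = build_release(sp, registry, particles_per_point=5)
        ens = advect(rel, default_field, seed=9)
        arr = detect_arrivals(ens, registry)
        c = connection_matrix(arr, ens.released_per_origin,
                              [s.mpa_id for s in registry])
        rec = recruitment_fractions(c)
        defined = rec["defined"]
        assert defined.any()
        total = rec.loc[defined, "selfr"] + rec.loc[defined, "subr"]
        assert np.allclose(total, 1.0, atol=1e-12)


class TestAggregation:
    def make_c(self, vals):
        return pd.DataFrame(vals, index=["A", "B"], columns=["A", "B"],
                            dtype=float)

    def test_idempotence_for_identical_inputs(self):
        c = self.make_c([[0.5, 0.1], [0.0, 0.2]])
        agg = aggregate_species({"s1": c, "s2": c}, {"s1": 0.5, "s2": 0.5})
        assert np.allclose(agg, c)

    def test_degenerate_weights_select_one_species(self):
        c1 = self.make_c([[1.0, 0.0], [0.0, 0.0]])
        c2 = self.make_c([[0.0, 1.0], [0.0, 0.0]])
        agg = aggregate_species({"s1": c1, "s2": c2}, {"s1": 1.0, "s2": 0.0})
        assert np.array_equal(agg.to_numpy(), c1.to_numpy())

    def test_category_weights_split_evenly_within_group(self, species_table):
        """9 threatened and 5 economic species: each group totals 0.5."""
        w = category_weights(species_table)
        threatened = [s.name for s in species_table if s.category == "threatened"]
        economic = [s.name for s in species_table if s.category == "economic"]
        assert len(threatened) == 9 and len(economic) == 5
        for name in threatened:
            assert w[name] == pytest.approx(0.5 / 9)
        for name in economic:
            assert w[name] == pytest.approx(0.5 / 5)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_weights_must_sum_to_one(self):
        c = self.make_c([[0.1, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="sum to 1"):
            aggregate_species({"s1": c}, {"s1": 0.9})


class TestEdgeList:
    def test_offdiagonal_thresholded_with_demographic_flag(self):
        c = pd.DataFrame([[0.9, 0.02, 0.0005], [0.0, 0.0, 0.0],
                          [0.0, 0.0, 0.5]],
                         index=list("ABC"), columns=list("ABC"))
        edges = edge_list(c)
        assert len(edges) == 2  # diagonal excluded, zeros excluded
        ab = edges[(edges.origin == "A") & (edges.destination == "B")]
        ac = edges[(edges.origin == "A") & (edges.destination == "C")]
        assert bool(ab["demographic"].iloc[0]) is True
        assert bool(ac["demographic"].iloc[0]) is False
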