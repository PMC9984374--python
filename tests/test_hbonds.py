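import numpy as np
import pytest

import confspec as cs
from confspec.hbonds import (
    KB_KCAL,
    HBondModel,
    TripletGeometry,
    count,
    enumerate_triplets,
    integrate_cells,
    per_cluster_summary,
    surface,
)

from _oracles import triplets_bruteforce


def _triplet(d_dh, d_ah, d_da):
    return TripletGeometry(d_DH=d_dh, d_AH=d_ah, d_DA=d_da,
                           donor_id=0, hydrogen_id=1, acceptor_id=2)


# -- enumeration -------------------------------------------------------------

def test_no_donors_or_acceptors_gives_empty_list():
    # an alkane-like fragment: C and H only
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.1, 0], [1.5, 1.1, 0.0]],
                      dtype=float)
    assert enumerate_triplets(coords, ["C", "C", "H", "H"]) == []


def test_single_nh_plus_oxygen_gives_one_triplet():
    coords = np.array([[0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]], dtype=float)
    trips = enumerate_triplets(coords, ["N", "H", "O"])
    assert len(trips) == 1
    t = trips[0]
    assert t.donor_id == 0 and t.hydrogen_id == 1 and t.acceptor_id == 2
    assert t.d_DA == pytest.approx(2.9)
    assert t.d_AH == pytest.approx(1.9)


def test_enumeration_matches_bruteforce_on_generated_frame(three_basins):
    ens, _ = cs.generate_ensemble(three_basins, 3, seed=5)
    for f in range(ens.n_frames):
        got = enumerate_triplets(ens.coords[f], ens.species)
        expected = triplets_bruteforce(ens.coords[f], ens.species)
        assert len(got) == len(expected)
        for t, (d, h, a, ddh, dah, dda) in zip(got, expected):
            assert (t.donor_id, t.hydrogen_id, t.acceptor_id) == (d, h, a)
            assert t.d_DH == pytest.approx(ddh)
            assert t.d_AH == pytest.approx(dah)
            assert t.d_DA == pytest.approx(dda)


def test_covalently_adjacent_acceptor_excluded():
    # O two bonds from N (N-C=O) must not count as an acceptor for that N
    coords = np.array(
        [[0, 0, 0], [1.0, 0.3, 0], [1.4, -0.6, 0.0], [2.4, -1.2, 0.0]],
        dtype=float,
    )
    trips = enumerate_triplets(coords, ["N", "H", "C", "O"])
    assert trips == []


# -- membership --------------------------------------------------------------

def test_membership_reference_geometry_is_near_one():
    model = HBondModel()
    assert model.membership(_triplet(1.0, 1.9, 2.9)) >= 0.99


def test_membership_dissociated_limit():
    model = HBondModel()
    assert model.membership(_triplet(1.0, 9.0, 10.0)) <= 1e-6


def test_membership_equals_mixture_posterior_formula():
    model = HBondModel()
    t = _triplet(1.05, 2.2, 3.1)
    nu, mu, dda = t.d_DH - t.d_AH, t.d_DH + t.d_AH, t.d_DA
    g = 1.0
    for x, m, s in zip((nu, mu, dda), model.mean, model.sd):
        g *= np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    vol = np.prod([hi - lo for lo, hi in model.background_box])
    expected = 0.5 * g / (0.5 * g + 0.5 / vol)
    assert model.membership(t) == pytest.approx(expected, abs=1e-12)


def test_membership_decays_with_acceptor_distance():
    model = HBondModel()
    vals = [
        model.membership(_triplet(1.0, d - 1.0, d))
        for d in np.linspace(2.9, 8.0, 30)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


# -- counting ----------------------------------------------------------------

def test_count_empty_frame_has_no_entries():
    coords = np.array([[0, 0, 0], [1.5, 0, 0]], dtype=float)
    counts = count(coords, ["C", "C"])
    assert counts.s_D == {} and counts.s_A == {} and counts.s_H == {}
    assert counts.frame_mean("D") is None


def test_ammonium_donor_with_two_ideal_acceptors_counts_two():
    """An NH3+-like donor hydrogen-bonded to two ideal acceptors has
    s_D = 2: only the terminal amine can donate more than one bond."""
    # tetrahedral-ish N-H directions
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1]], dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = [np.zeros(3)]
    species = ["N"]
    for u in dirs:
        coords.append(1.01 * u)
        species.append("H")
    for u in dirs[:2]:  # two acceptors, collinear with two N-H bonds
        coords.append(2.9 * u)
        species.append("O")
    counts = count(np.array(coords), species)
    assert counts.s_D[0] == pytest.approx(2.0, abs=0.02)
    # both acceptors accept ~1
    for o in (4, 5):
        assert counts.s_A[o] == pytest.approx(1.0, abs=0.01)


def test_count_matches_exhaustive_sum(three_basins):
    ens, _ = cs.generate_ensemble(three_basins, 2, seed=8)
    model = HBondModel()
    for f in range(ens.n_frames):
        counts = count(ens.coords[f], ens.species, model)
        trips = enumerate_triplets(ens.coords[f], ens.species)
        s_d: dict = {}
        for t in trips:
            s_d[t.donor_id] = s_d.get(t.donor_id, 0.0) + model.membership(t)
        assert counts.s_D == pytest.approx(s_d)


# -- probability surfaces ----------------------------------------------------

def test_equal_probability_bins_have_zero_free_energy_gap():
    samples = np.array([0.52] * 40 + [1.52] * 40)
    surf = surface(samples, temperature=300.0)
    f = surf.free_energy
    c = surf.centers[0]
    f1 = f[np.argmin(np.abs(c - 0.52))]
    f2 = f[np.argmin(np.abs(c - 1.52))]
    assert f1 == pytest.approx(f2, abs=1e-12)


def test_two_to_one_ratio_gives_kT_log_two():
    samples = np.array([0.52] * 200 + [1.52] * 100)
    surf = surface(samples, temperature=300.0)
    c = surf.centers[0]
    f = surf.free_energy
    df = f[np.argmin(np.abs(c - 1.52))] - f[np.argmin(np.abs(c - 0.52))]
    assert df == pytest.approx(KB_KCAL * 300.0 * np.log(2.0), abs=0.005)
    assert df == pytest.approx(0.413, abs=0.005)


def test_smoothing_conserves_total_probability(rng):
    samples = rng.uniform(0, 3, size=500)
    for width in (0.025, 0.2, 0.6):
        surf = surface(samples, width=width)
        assert abs(surf.probability.sum() - 1.0) < 1e-9


def test_free_energy_differences_scale_invariant():
    base = np.array([0.3] * 30 + [1.1] * 60 + [2.2] * 10)
    s1 = surface(base)
    s3 = surface(np.repeat(base, 3))  # tripled counts
    f1, f3 = s1.free_energy, s3.free_energy
    ok = ~np.isnan(f1) & ~np.isnan(f3)
    d1 = f1[ok] - f1[ok][0]
    d3 = f3[ok] - f3[ok][0]
    assert np.allclose(d1, d3, atol=1e-9)


def test_temperature_must_be_positive():
    with pytest.raises(ValueError):
        surface(np.array([1.0]), temperature=-5.0)


# -- integer-cell integration ------------------------------------------------

def test_all_mass_in_one_cell():
    samples = np.column_stack([np.full(50, 1.0), np.full(50, 2.0)])
    surf = surface(samples)
    cells, best, pct = integrate_cells(surf)
    assert best == (1, 2)
    assert pct == pytest.approx(100.0, abs=1e-6)


def test_constructed_42_percent_cell():
    rng = np.random.default_rng(0)
    n = 100
    a = np.column_stack([np.full(42, 1.0), np.full(42, 2.0)])
    b = np.column_stack([np.full(30, 1.0), np.full(30, 1.0)])
    c = np.column_stack([np.full(28, 2.0), np.full(28, 1.0)])
    surf = surface(np.concatenate([a, b, c]))
    cells, best, pct = integrate_cells(surf)
    assert best == (1, 2)
    assert pct == pytest.approx(42.0, abs=1e-6)


def test_cell_masses_partition_unity(rng):
    samples = rng.uniform(0, 3, size=(400, 2))
    surf = surface(samples, width=0.1)
    cells, _best, _pct = integrate_cells(surf)
    assert sum(cells.values()) == pytest.approx(100.0, abs=1e-6)


# -- per-cluster summary -----------------------------------------------------

class _FakeCounts:
    def __init__(self, sa, sd):
        self._sa, self._sd = sa, sd

    def frame_mean(self, role):
        return {"A": self._sa, "D": self._sd}[role]


def test_summary_single_frame_single_donor():
    counts = [_FakeCounts(1.0, 1.0)]
    df = per_cluster_summary(counts, np.array([0]), np.array([1.0]))
    assert df.loc[0, "mean_sD"] == pytest.approx(1.0)
    assert df.loc[0, "sd_sD"] == pytest.approx(0.0)


def test_summary_population_standard_deviation():
    counts = [_FakeCounts(1.0, 1.0), _FakeCounts(1.0, 2.0)]
    df = per_cluster_summary(counts, np.array([0, 0]), np.array([1.0]))
    assert df.loc[0, "mean_sD"] == pytest.approx(1.5)
    assert df.loc[0, "sd_sD"] == pytest.approx(0.5)  # population sd


def test_summary_schema_and_missing_cluster_fields():
    counts = [_FakeCounts(1.0, 2.0), _FakeCounts(None, None)]
    df = per_cluster_summary(
        counts, np.array([0, 1]), np.array([0.5, 0.5])
    )
    assert list(df.columns) == [
        "cluster", "mean_sA", "sd_sA", "mean_sD", "sd_sD",
        "mp_tuple", "mp_pct", "weight_pct",
    ]
    assert np.isnan(df.loc[1, "mean_sD"])  # absent, not zero
    assert df.loc[1, "mp_tuple"] == ""
    assert df.loc[0, "weight_pct"] == pytest.approx(50.0)


def test_per_basin_occupancy_recovered(three_basins):
    """Basins engineered to donate 1, 2 and 1 hydrogen bonds are recovered
    by the per-cluster averages using the true labels."""
    from dataclasses import replace

    # tight torsion spread isolates the prescribed probe H-bonds from
    # incidental backbone contacts
    basins = [
        replace(b, torsion_concentrations=(400.0,) * 4) for b in three_basins
    ]
    ens, truth = cs.generate_ensemble(basins, 300, seed=21)
    counts = cs.count_ensemble(ens)
    ids = np.array([b.id for b in basins])
    labels = np.searchsorted(ids, truth.frame_labels)
    weights = np.bincount(labels) / len(labels)
    df = per_cluster_summary(counts, labels, weights)
    for k, b in enumerate(basins):
        assert df.loc[k, "mean_sD"] == pytest.approx(b.n_acceptors, abs=0.1)
        assert df.loc[k, "mean_sA"] == pytest.approx(1.0, abs=0.1)


def test_counts_and_surface_tables(three_basins):
    from confspec.hbonds import counts_to_frame, surface_to_frame

    ens, _ = cs.generate_ensemble(three_basins, 3, seed=2)
    counts = cs.count_ensemble(ens)
    table = counts_to_frame(counts)
    assert list(table.columns) == ["frame", "atom_id", "role", "value"]
    assert set(table.role) <= {"D", "A", "H"}
    assert (table.value >= 0).all()

    surf = surface(np.column_stack([np.full(20, 1.0), np.full(20, 2.0)]))
    grid = surface_to_frame(surf)
    assert {"s_A", "s_D", "probability", "free_energy"} <= set(grid.columns)
    assert grid.probability.sum() == pytest.approx(1.0, abs=1e-9)
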