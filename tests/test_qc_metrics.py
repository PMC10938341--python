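import numpy as np
import pandas as pd
import pytest

import surfqc as sq
from _oracles import euler_characteristic, mad_plain
from surfqc.errors import DomainError, EmptyInputError, SchemaError
from surfqc.fs_io import CohortSchema, CohortTable, TriMesh
from surfqc.qc_metrics import harmonize_supplied_euler


# -- topology ---------------------------------------------------------------


def test_icosahedron_textbook_counts():
    topo = sq.mesh_topology(sq.make_icosphere(0))
    assert (topo.n_vertices, topo.n_edges, topo.n_faces) == (12, 30, 20)
    assert topo.euler_characteristic == 2
    assert topo.defect_index == 0
    assert topo.n_components == 1


@pytest.mark.parametrize("m,n", [(3, 3), (5, 4), (48, 24)])
def test_torus_grid_counts(m, n):
    topo = sq.mesh_topology(sq.make_torus(30, 10, m, n))
    assert (topo.n_vertices, topo.n_edges, topo.n_faces) == (m * n, 3 * m * n, 2 * m * n)
    assert topo.euler_characteristic == 0
    assert topo.defect_index == 1


@pytest.mark.parametrize("g", [1, 2, 3])
def test_handles_reduce_chi_by_two_each(g):
    mesh = sq.make_icosphere(2, radius=50.0)
    for i in range(g):
        mesh = sq.add_handle(mesh, seed=100 + i)
        assert sq.mesh_topology(mesh).euler_characteristic == euler_characteristic(mesh.faces)
    topo = sq.mesh_topology(mesh)
    assert topo.euler_characteristic == 2 - 2 * g
    assert topo.defect_index == g


def test_chi_invariant_under_random_permutation():
    rng = np.random.default_rng(21)
    mesh = sq.add_handle(sq.make_icosphere(2, radius=30.0), seed=0)
    chi = sq.mesh_topology(mesh).euler_characteristic
    for _ in range(20):
        perm = rng.permutation(mesh.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = TriMesh(vertices=mesh.vertices[perm], faces=inv[mesh.faces][rng.permutation(mesh.n_faces)])
        assert sq.mesh_topology(shuffled).euler_characteristic == chi


def test_two_component_mesh_counted():
    a = sq.make_icosphere(1, radius=10.0)
    b = sq.make_icosphere(1, radius=10.0, center=(50, 0, 0))
    merged = TriMesh(
        vertices=np.vstack([a.vertices, b.vertices]),
        faces=np.vstack([a.faces, b.faces + a.n_vertices]),
    )
    topo = sq.mesh_topology(merged)
    assert topo.n_components == 2
    assert topo.euler_characteristic == 4


def test_subject_euler_index():
    assert sq.subject_euler_index(0, 0) == 0
    assert sq.subject_euler_index(3, 4) == 7
    with pytest.raises(DomainError):
        sq.subject_euler_index(-1, 0)


def test_supplied_signed_euler_harmonization_preserves_ordering():
    rng = np.random.default_rng(13)
    defects = rng.integers(0, 40, size=(50, 2))
    computed = defects.sum(axis=1)
    # FreeSurfer-style signed per-hemisphere chi = 2 - 2 d, summed
    supplied = (2 - 2 * defects).sum(axis=1)
    harmonized = harmonize_supplied_euler(supplied - 4)  # |sum chi - 4| = 2 (dl + dr)
    rho, _ = sq.spearman_rho(harmonized.astype(float), computed.astype(float))
    assert rho > 0.999


# -- MAD --------------------------------------------------------------------


def test_mad_hand_values():
    assert sq.mad([1, 2, 3, 4, 5]) == 1.0
    assert sq.mad([7, 7, 7]) == 0.0
    with pytest.raises(EmptyInputError):
        sq.mad([])


def test_mad_normal_consistency():
    rng = np.random.default_rng(99)
    x = rng.standard_normal(100_000)
    assert sq.mad(x, scale_constant=1.4826) == pytest.approx(1.0, rel=0.02)


def test_mad_thresholds_and_monotonicity():
    np.testing.assert_allclose(sq.mad_thresholds([1, 2, 3, 4, 5], [1, 2]), [4.0, 5.0])
    rng = np.random.default_rng(5)
    x = rng.lognormal(4.6, 0.8, 500)
    th = sq.mad_thresholds(x, [1, 1.5, 2])
    assert np.all(np.diff(th) > 0)
    for k, t in zip([1, 1.5, 2], th):
        assert t == pytest.approx(np.median(x) + k * mad_plain(x), abs=1e-9)


def test_mad_thresholds_per_group_matches_pooled_formula_within_group():
    rng = np.random.default_rng(8)
    a = rng.normal(100, 10, 200)
    b = rng.normal(300, 30, 200)
    values = np.concatenate([a, b])
    groups = np.array(["A"] * 200 + ["B"] * 200)
    table = sq.mad_thresholds(values, [1, 2], groups=groups)
    np.testing.assert_allclose(table.loc["A"], sq.mad_thresholds(a, [1, 2]))
    np.testing.assert_allclose(table.loc["B"], sq.mad_thresholds(b, [1, 2]))
    assert not np.allclose(table.loc["A"], table.loc["B"])


# -- quality filter ---------------------------------------------------------


def _toy_cohort(scores, sites=None, dx=None):
    n = len(scores)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": 10.0,
            "sex": 0,
            "diagnosis": dx if dx is not None else [0] * n,
            "site": sites if sites is not None else ["A"] * n,
            "fsqc": scores,
        }
    )
    return CohortTable(df, CohortSchema(qc_metrics=("fsqc",)))


def test_absolute_cutoff_retains_boundary():
    cohort = _toy_cohort([1.1, 2.5, 2.6, 4.0])
    res = sq.apply_quality_filter(cohort, sq.FSQC_METRIC, cutoff=2.5, mode="absolute")
    assert sorted(res.retained.df["fsqc"]) == [1.1, 2.5]
    assert res.report.n_excluded == 2
    strict = sq.apply_quality_filter(
        cohort, sq.FSQC_METRIC, cutoff=2.5, mode="absolute", strict=True
    )
    assert sorted(strict.retained.df["fsqc"]) == [1.1]


def test_higher_better_direction_flips_retention():
    cohort = _toy_cohort([10.0, 40.0, 80.0, 95.0])
    metric = sq.QCMetricSpec("fsqc", "higher_better")
    res = sq.apply_quality_filter(cohort, metric, cutoff=40.0, mode="absolute")
    assert sorted(res.retained.df["fsqc"]) == [40.0, 80.0, 95.0]


def test_median_split_ties_to_lower_group():
    cohort = _toy_cohort([1, 1, 1, 2, 2, 3, 3, 4, 4, 4])
    res = sq.apply_quality_filter(cohort, sq.FSQC_METRIC, mode="median_split")
    assert res.groups.value_counts()["low"] == 5
    assert res.groups.value_counts()["high"] == 5


def test_mad_k_equals_absolute_at_derived_cutoff():
    rng = np.random.default_rng(31)
    scores = np.round(rng.uniform(1, 4, 60), 2)
    cohort = _toy_cohort(scores)
    via_mad = sq.apply_quality_filter(cohort, sq.FSQC_METRIC, mode="mad_k", k=2)
    cutoff = np.median(scores) + 2 * mad_plain(scores)
    via_abs = sq.apply_quality_filter(cohort, sq.FSQC_METRIC, cutoff=cutoff, mode="absolute")
    assert list(via_mad.retained.df["subject_id"]) == list(via_abs.retained.df["subject_id"])


def test_filter_monotone_and_partition():
    rng = np.random.default_rng(17)
    scores = rng.uniform(1, 4, 100)
    dx = rng.integers(0, 2, 100)
    sites = rng.choice(["A", "B", "C"], 100)
    cohort = _toy_cohort(scores, sites=sites, dx=dx)
    sizes = []
    for cutoff in (3.5, 3.0, 2.5, 2.0, 1.5):
        res = sq.apply_quality_filter(cohort, sq.FSQC_METRIC, cutoff=cutoff, mode="absolute")
        sizes.append(res.report.n_retained)
        assert res.report.n_retained + res.report.n_excluded == res.report.n_input
        assert sum(res.report.by_site.values()) == res.report.n_excluded
    assert sizes == sorted(sizes, reverse=True)


def test_per_site_mad_filter_uses_site_cutoffs():
    scores = np.concatenate([np.linspace(1, 2, 30), np.linspace(2.5, 4, 30)])
    sites = np.array(["A"] * 30 + ["B"] * 30)
    cohort = _toy_cohort(scores, sites=sites)
    res = sq.apply_quality_filter(cohort, sq.FSQC_METRIC, mode="mad_k", k=1, per_site=True)
    # each site loses its own tail, so both sites keep most rows
    kept = res.retained.df["site"].value_counts()
    assert kept["A"] >= 20 and kept["B"] >= 20


def test_unknown_mode_and_missing_metric():
    cohort = _toy_cohort([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(Exception):
        sq.apply_quality_filter(cohort, sq.FSQC_METRIC, cutoff=2, mode="nonsense")
    with pytest.raises(SchemaError):
        sq.apply_quality_filter(cohort, sq.QCMetricSpec("missing"), cutoff=2)
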