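import numpy as np
import pytest
from scipy.stats import qmc

from scnhpa.population import (DEFAULT_RANGES, accept, build_cohort,
                               cohort_report, nominal_cort_cycle,
                               sobol_sample)


def test_sobol_determinism_and_ranges():
    a = sobol_sample(32, DEFAULT_RANGES, seed=3)
    b = sobol_sample(32, DEFAULT_RANGES, seed=3)
    c = sobol_sample(32, DEFAULT_RANGES, seed=4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
    lo = [DEFAULT_RANGES[k][0] for k in ("v_l", "v_c2", "v_coe")]
    hi = [DEFAULT_RANGES[k][1] for k in ("v_l", "v_c2", "v_coe")]
    assert np.all(a >= lo) and np.all(a <= hi)
    with pytest.raises(ValueError):
        sobol_sample(4)


def test_unscrambled_sequence_starts_at_known_points():
    """The unscrambled Sobol sequence opens with the origin and the cube
    centre, in every dimension."""
    ranges = {"v_l": (0.0, 1.0), "v_c2": (0.0, 1.0), "v_coe": (0.0, 1.0)}
    pts = sobol_sample(8, ranges, seed=0, scramble=False)
    np.testing.assert_array_equal(pts[0], [0.0, 0.0, 0.0])
    np.testing.assert_array_equal(pts[1], [0.5, 0.5, 0.5])
    assert len(np.unique(pts, axis=0)) == 8


def test_sobol_beats_iid_uniform_discrepancy():
    """Low-discrepancy design: centred discrepancy below i.i.d. sampling
    at n = 256."""
    unit = {"v_l": (0.0, 1.0), "v_c2": (0.0, 1.0), "v_coe": (0.0, 1.0)}
    sob = sobol_sample(256, unit, seed=0)
    iid = np.random.default_rng(0).uniform(size=(256, 3))
    assert qmc.discrepancy(sob) < qmc.discrepancy(iid)


@pytest.fixture(scope="module")
def nominal_cycle(nominal):
    return nominal_cort_cycle(nominal)


def test_nominal_triple_accepted(nominal, nominal_cycle):
    flag, reason = accept(nominal, nominal_cycle)
    assert flag and reason == "ok"


def test_fully_uncoupled_candidate_rejected(nominal, nominal_cycle):
    cand = nominal.with_updates(v_l=0, v_c2=0, v_coe=0)
    flag, reason = accept(cand, nominal_cycle)
    assert not flag and reason == "not_entrained"


def test_band_tightening_is_monotone(nominal, nominal_cycle):
    """Any candidate accepted at a 10% band is accepted at 20%."""
    triples = [(0.25, 1.01, 0.85), (0.3, 1.2, 0.9), (0.15, 1.5, 0.7),
               (0.4, 0.5, 0.85), (0.05, 1.01, 0.85)]
    for vl, vc2, vcoe in triples:
        cand = nominal.with_updates(v_l=vl, v_c2=vc2, v_coe=vcoe)
        tight, _ = accept(cand, nominal_cycle, band=0.10)
        loose, _ = accept(cand, nominal_cycle, band=0.20)
        assert (not tight) or loose


def test_cohort_reproducible(nominal):
    a = build_cohort(nominal, n=16, seed=9)
    b = build_cohort(nominal, n=16, seed=9)
    assert a.to_frame().equals(b.to_frame())


def test_cohort_report_structure(cohort64):
    rep = cohort_report(cohort64)
    assert rep["n_candidates"] == 64
    assert rep["n_accepted"] == len(cohort64.accepted) > 0
    assert set(rep["groups"]) == {"A", "B"}
    assert "spearman" in rep
    # accepted region respects the published coupling thresholds
    assert rep["min_accepted"]["v_l"] >= 0.1
    assert rep["min_accepted"]["v_c2"] >= 0.8


def test_accepted_have_narrow_avp_coupling(cohort64):
    """The accepted v_coe values cluster tightly around the nominal 0.85,
    unlike the broad v_l and v_c2 spreads."""
    acc = cohort64.accepted
    vcoe = [i.v_coe for i in acc]
    assert max(vcoe) - min(vcoe) < 0.5
    assert all(0.4 <= v <= 1.2 for v in vcoe)
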