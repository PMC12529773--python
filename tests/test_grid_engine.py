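import numpy as np
import pytest

from ncitraj.grid_engine import (
    NCIParams,
    PairIntegrals,
    build_pair_grid,
    classify_and_integrate,
    connected_components,
    evaluate_nci_fields,
    pair_integrals,
    read_cube,
    select_interaction_points,
    write_cube,
)
from ncitraj.promolecular import BOHR_PER_ANGSTROM


def test_nciparams_validation():
    with pytest.raises(ValueError):
        NCIParams(spacing=0.0)
    with pytest.raises(ValueError):
        NCIParams(frag_fraction=0.6)
    with pytest.raises(ValueError):
        NCIParams(thresholds=(0.02, -0.02))
    with pytest.raises(ValueError):
        NCIParams(refine_resolution=-1.0)
    assert NCIParams(spacing=0.1).refine_factor == 4
    assert NCIParams(spacing=0.1, refine_resolution=None).refine_factor == 1


def test_build_pair_grid_contains_all_atoms(hbond_dimer):
    spec = build_pair_grid(hbond_dimer.fragA, hbond_dimer.fragB, spacing=0.25, margin=2.0)
    coords = np.vstack([hbond_dimer.fragA.coords, hbond_dimer.fragB.coords])
    coords_b = coords * BOHR_PER_ANGSTROM
    lo = np.asarray(spec.origin)
    hi = lo + (np.asarray(spec.shape) - 1) * spec.spacing
    margin_b = 2.0 * BOHR_PER_ANGSTROM
    assert np.all(coords_b - lo >= margin_b - 1e-9)
    assert np.all(hi - coords_b >= -1e-9)  # box extends past every atom


def test_grid_points_c_order_z_fastest():
    spec = build_pair_grid(
        [("H", (0.0, 0.0, 0.0))], [("H", (1.0, 1.0, 1.0))], spacing=0.5, margin=2.0
    )
    pts = spec.points() * BOHR_PER_ANGSTROM
    # first two points differ only along z by one spacing
    np.testing.assert_allclose(pts[1] - pts[0], [0, 0, spec.spacing], atol=1e-12)


def test_selection_mask_bounds(hbond_dimer):
    spec = build_pair_grid(hbond_dimer.fragA, hbond_dimer.fragB, spacing=0.4)
    grid = evaluate_nci_fields(spec, hbond_dimer.fragA, hbond_dimer.fragB)
    mask = select_interaction_points(grid)
    assert mask.any()
    rho = grid.rho_total[mask]
    assert np.all(rho < 0.05) and np.all(rho > 0)
    assert np.all(grid.s[mask] < 1.0)
    minor = np.minimum(grid.rho_fragA, grid.rho_fragB)[mask] / rho
    assert np.all(minor >= 0.05)


def test_classify_partition_is_exact(hbond_dimer):
    spec = build_pair_grid(hbond_dimer.fragA, hbond_dimer.fragB, spacing=0.4)
    grid = evaluate_nci_fields(spec, hbond_dimer.fragA, hbond_dimer.fragB)
    mask = select_interaction_points(grid)
    res = classify_and_integrate(grid, mask)
    assert res.attractive + res.vdw + res.repulsive == pytest.approx(res.total, rel=1e-15)
    # ties at the threshold go to vdW: shift thresholds so everything is vdW
    wide = classify_and_integrate(grid, mask, thresholds=(-10.0, 10.0))
    assert wide.attractive == 0.0 and wide.repulsive == 0.0
    assert wide.vdw == pytest.approx(res.total, rel=1e-12)


def test_empty_mask_gives_zero_integrals(hbond_dimer):
    spec = build_pair_grid(hbond_dimer.fragA, hbond_dimer.fragB, spacing=0.5)
    grid = evaluate_nci_fields(spec, hbond_dimer.fragA, hbond_dimer.fragB)
    res = classify_and_integrate(grid, np.zeros(spec.n_voxels, dtype=bool))
    assert res.total == 0.0


def test_pair_integrals_invalid_partition_rejected():
    with pytest.raises(ValueError):
        PairIntegrals(0, ("A", "B"), 1.0, 1.0, 1.0, 5.0)
    with pytest.raises(ValueError):
        PairIntegrals(0, ("A", "B"), -1.0, 0.0, 0.0, -1.0)


def test_fast_path_unrefined_equals_full_route(hbond_dimer):
    params = NCIParams(spacing=0.3, refine_resolution=None)
    fast = pair_integrals(hbond_dimer.fragA, hbond_dimer.fragB, params)
    spec = build_pair_grid(hbond_dimer.fragA, hbond_dimer.fragB, spacing=0.3)
    grid = evaluate_nci_fields(spec, hbond_dimer.fragA, hbond_dimer.fragB)
    full = classify_and_integrate(grid, select_interaction_points(grid))
    assert fast.attractive == full.attractive
    assert fast.vdw == full.vdw
    assert fast.repulsive == full.repulsive


def test_refined_quadrature_insensitive_to_nominal_spacing(hbond_dimer):
    # With the quadrature resolution held fixed, the nominal scan spacing only
    # controls coverage; integrals must agree closely across spacings.
    p1 = NCIParams(spacing=0.2, refine_resolution=0.025)
    p2 = NCIParams(spacing=0.1, refine_resolution=0.025)
    r1 = pair_integrals(hbond_dimer.fragA, hbond_dimer.fragB, p1)
    r2 = pair_integrals(hbond_dimer.fragA, hbond_dimer.fragB, p2)
    assert r1.total == pytest.approx(r2.total, rel=0.02)
    assert r1.attractive == pytest.approx(r2.attractive, rel=0.02)


def test_distant_fragments_have_zero_integrals():
    fragA = [("O", (0.0, 0.0, 0.0)), ("H", (0.96, 0.0, 0.0))]
    fragB = [("O", (30.0, 0.0, 0.0)), ("H", (30.96, 0.0, 0.0))]
    res = pair_integrals(fragA, fragB, NCIParams(spacing=0.5, refine_resolution=None))
    assert res.total == 0.0


def test_connected_components_labels_mask(hbond_dimer):
    spec = build_pair_grid(hbond_dimer.fragA, hbond_dimer.fragB, spacing=0.4)
    grid = evaluate_nci_fields(spec, hbond_dimer.fragA, hbond_dimer.fragB)
    mask = select_interaction_points(grid)
    labels = connected_components(grid, mask)
    assert labels.shape == spec.shape
    assert labels.max() >= 1


def test_cube_round_trip(tmp_path, hbond_dimer):
    spec = build_pair_grid(hbond_dimer.fragA, hbond_dimer.fragB, spacing=0.5)
    grid = evaluate_nci_fields(spec, hbond_dimer.fragA, hbond_dimer.fragB)
    atoms = hbond_dimer.fragA.atoms() + hbond_dimer.fragB.atoms()
    path = tmp_path / "rho.cube"
    write_cube(spec, grid.rho_total, atoms, path)
    spec2, vals, atoms2 = read_cube(path)
    assert spec2.shape == spec.shape
    np.testing.assert_allclose(spec2.origin, spec.origin, atol=1e-5)
    np.testing.assert_allclose(vals.ravel(), grid.rho_total, rtol=2e-5)
    assert len(atoms2) == len(atoms)
    assert atoms2[0][0] == 7  # first donor atom is nitrogen
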