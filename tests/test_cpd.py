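import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from neuromotif.cpd import (AlignmentError, CPDConfig, cpd_rigid_rotation,
                            dissimilarity_matrix, e_step, nearest_neuron,
                            pair_dissimilarity)
from neuromotif.topography import rotation_geodesic_deg


def neuronlike_cloud(n=200, seed=0):
    """Soma-centered cloud shaped like an axon: trunk plus terminal blob."""
    rng = np.random.default_rng(seed)
    tip = np.array([300.0, 1800.0, 500.0])
    n_trunk = n // 4
    trunk = np.linspace(0, 1, n_trunk)[:, None] * tip
    blob = tip + rng.normal(0, 150.0, size=(n - n_trunk, 3))
    return np.vstack([trunk, blob])


def test_self_alignment_identity():
    cloud = neuronlike_cloud(120, 1)
    res = cpd_rigid_rotation(cloud, cloud)
    assert rotation_geodesic_deg(res.rotation, np.eye(3)) < 0.1
    assert res.mse < 1e-6


def test_rotation_recovery_matches_kabsch():
    """A 25-degree rotation is recovered and agrees with the closed-form
    orthogonal-Procrustes solution given the true correspondences."""
    cloud = neuronlike_cloud(200, 2)
    R_true = Rotation.from_euler("y", 25, degrees=True).as_matrix()
    ref = cloud @ R_true.T
    res = cpd_rigid_rotation(cloud, ref)
    assert rotation_geodesic_deg(res.rotation, R_true) < 1.0
    assert res.mse < 1.0

    # Kabsch oracle with known correspondences
    A = ref.T @ cloud
    U, _s, Vt = np.linalg.svd(A)
    C = np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))])
    R_kabsch = U @ C @ Vt
    assert rotation_geodesic_deg(res.rotation, R_kabsch) < 1.0


@pytest.mark.parametrize("w", [0.0, 0.2])
def test_e_step_matches_hand_enumeration(w):
    """Responsibilities on tiny clouds equal the explicitly enumerated
    Gaussian posteriors with the uniform outlier term."""
    moving = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0]])
    reference = np.array([[0.1, 0, 0], [1, 0.2, 0], [0, 1.8, 0.3],
                          [2, 2, 2]])
    R = Rotation.from_euler("z", 10, degrees=True).as_matrix()
    sigma2 = 0.7
    P, _nll = e_step(moving, reference, R, sigma2, w)
    M, N = len(moving), len(reference)
    moved = moving @ R.T
    expected = np.zeros((M, N))
    c = (2 * np.pi * sigma2) ** 1.5 * w * M / ((1 - w) * N)
    for n in range(N):
        ks = [np.exp(-np.sum((reference[n] - moved[m]) ** 2) / (2 * sigma2))
              for m in range(M)]
        for m in range(M):
            expected[m, n] = ks[m] / (sum(ks) + c)
    np.testing.assert_allclose(P, expected, atol=1e-10)


def test_objective_nonincreasing():
    cloud = neuronlike_cloud(80, 3)
    ref = cloud @ Rotation.from_euler("x", 40, degrees=True).as_matrix().T
    # re-run EM manually, tracking the negative log-likelihood
    from neuromotif.cpd import _D
    R = np.eye(3)
    d2 = ((ref[None] - cloud[:, None]) ** 2).sum(-1)
    sigma2 = d2.sum() / (_D * cloud.shape[0] * ref.shape[0])
    prev = np.inf
    for _ in range(40):
        P, nll = e_step(cloud, ref, R, sigma2, 0.0)
        assert nll <= prev + 1e-6
        prev = nll
        A = (P @ ref).T @ cloud
        U, _s, Vt = np.linalg.svd(A)
        R = U @ np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        Np = P.sum()
        xPx = (P.sum(axis=0) * (ref ** 2).sum(axis=1)).sum()
        yPy = (P.sum(axis=1) * (cloud ** 2).sum(axis=1)).sum()
        sigma2 = max((xPx - 2 * np.trace(A.T @ R) + yPy) / (Np * _D), 1e-12)


def test_rotation_always_proper():
    for seed in range(5):
        cloud = neuronlike_cloud(60, seed)
        ref = neuronlike_cloud(60, seed + 10)
        res = cpd_rigid_rotation(cloud, ref, CPDConfig(max_iter=20))
        np.testing.assert_allclose(res.rotation.T @ res.rotation, np.eye(3),
                                   atol=1e-8)
        assert np.linalg.det(res.rotation) > 0


def test_degenerate_and_noncentered_inputs():
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    blob = neuronlike_cloud(30, 4)
    with pytest.raises(AlignmentError, match="rank|3 points"):
        cpd_rigid_rotation(line, blob)
    with pytest.raises(AlignmentError, match="3 points"):
        cpd_rigid_rotation(blob[:2], blob)
    far = blob + np.array([50_000.0, 0, 0])
    with pytest.raises(AlignmentError, match="soma-centered"):
        cpd_rigid_rotation(far, blob)


def test_noise_floor():
    """Registering a cloud against a noisy copy lands near the 3-sigma^2
    floor (hard correspondences can only bias it downward by a bounded
    factor)."""
    rng = np.random.default_rng(5)
    cloud = rng.uniform(-1000, 1000, size=(150, 3))
    for sigma in (1.0, 10.0):
        ref = cloud + rng.normal(0, sigma, size=cloud.shape)
        res = cpd_rigid_rotation(cloud, ref)
        floor = 3 * sigma ** 2
        assert floor / 2 <= res.mse <= floor * 2


def test_pair_dissimilarity_invariances(noiseless_minors):
    import dataclasses

    a = noiseless_minors[0]
    assert pair_dissimilarity(a, a) < 1e-6
    R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
    b = dataclasses.replace(
        a,
        branch_nodes=(a.branch_nodes - a.soma_point) @ R.T + a.soma_point,
        terminal_branches=[(br - a.soma_point) @ R.T + a.soma_point
                           for br in a.terminal_branches],
    )
    assert pair_dissimilarity(a, b) < 1.0

    # point-order relabeling does not change the dissimilarity
    order = np.random.default_rng(0).permutation(len(a.terminal_branches))
    c = dataclasses.replace(
        a, terminal_branches=[a.terminal_branches[i] for i in order])
    q = noiseless_minors[1]
    np.testing.assert_allclose(pair_dissimilarity(q, a),
                               pair_dissimilarity(q, c), rtol=1e-9)


def test_dissimilarity_matrix_properties(noiseless_minors):
    minors = noiseless_minors[:6] + [noiseless_minors[0]]  # duplicate
    D = dissimilarity_matrix(minors, CPDConfig(max_iter=30))
    n = len(minors)
    assert D.values.shape == (n, n)
    np.testing.assert_allclose(D.values, D.values.T, atol=1e-9)
    np.testing.assert_allclose(np.diag(D.values), 0.0)
    assert D.values[0, n - 1] < 1e-6  # duplicated neuron
    # entries match independent pair calls (modulo symmetrization)
    d01 = pair_dissimilarity(minors[0], minors[1])
    d10 = pair_dissimilarity(minors[1], minors[0])
    np.testing.assert_allclose(D.values[0, 1], 0.5 * (d01 + d10), rtol=1e-9)


def test_nearest_neuron_bruteforce(noiseless_minors):
    query = noiseless_minors[0]
    collection = noiseless_minors[1:6]
    nid, mse = nearest_neuron(query, collection)
    brute = [(pair_dissimilarity(query, c), c.neuron_id) for c in collection]
    best = min(brute)
    assert nid == best[1]
    assert mse == pytest.approx(best[0])
    # the collection containing the query itself wins with ~zero error
    nid2, mse2 = nearest_neuron(query, collection + [query])
    assert nid2 == query.neuron_id and mse2 < 1e-6
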