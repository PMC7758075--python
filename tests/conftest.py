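import numpy as np
import pytest

from lpiskf import LPISKF, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_study():
    """One desk-scale synthetic study shared across read-only tests."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_model(small_study):
    return LPISKF.from_synthetic(small_study)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def brute_force_auroc(scores, labels):
    """O(P*N) pairwise-comparison AUROC oracle, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_qp_oracle(x, neighbors):
    """Simplex-constrained least-squares by enumerating active sets.

    For each nonempty subset of neighbors, solve the equality-constrained
    KKT system min w'Gw s.t. sum(w)=1 restricted to the subset (lstsq handles
    the singular exact-reconstruction case) and keep the feasible solution
    with the smallest objective.
    """
    import itertools

    k = neighbors.shape[0]
    diff = x[None, :] - neighbors
    G = diff @ diff.T
    best_w, best_obj = None, np.inf
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(k), size):
            idx = list(subset)
            ks = len(idx)
            Gs = G[np.ix_(idx, idx)]
            kkt = np.zeros((ks + 1, ks + 1))
            kkt[:ks, :ks] = 2.0 * Gs
            kkt[:ks, ks] = 1.0
            kkt[ks, :ks] = 1.0
            rhs = np.zeros(ks + 1)
            rhs[ks] = 1.0
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            w_sub = sol[:ks]
            if (w_sub < -1e-9).any() or abs(w_sub.sum() - 1.0) > 1e-9:
                continue
            w = np.zeros(k)
            w[idx] = np.clip(w_sub, 0, None)
            w /= w.sum()
            obj = float(w @ G @ w)
            if obj < best_obj - 1e-12:
                best_obj, best_w = obj, w
    return best_w


def step_curve_aupr(scores, labels):
    """AUPR oracle: sum over descending unique thresholds of dR * precision."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    area = 0.0
    prev_rec = 0.0
    for t in sorted(np.unique(scores), reverse=True):
        called = scores >= t
        tp = np.sum(called & labels)
        prec = tp / called.sum()
        rec = tp / n_pos
        area += (rec - prev_rec) * prec
        prev_rec = rec
    return area
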