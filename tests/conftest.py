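import numpy as np
import pytest

from plbind import fixtures as fx


@pytest.fixture(scope="session")
def separable_data():
    """Standard 4-sigma-separated Gaussian class fixture (w=3)."""
    data, manifest = fx.gen_labeled_features(11, n_pos=60, n_neg=60, w=3, separation_sigma=4.0)
    return data, manifest


@pytest.fixture(scope="session")
def null_data():
    """Same shape, zero separation: labels carry no signal."""
    data, manifest = fx.gen_labeled_features(12, n_pos=60, n_neg=60, w=3, separation_sigma=0.0)
    return data, manifest


@pytest.fixture(scope="session")
def toy_complex():
    text, manifest = fx.gen_complex(1, n_residues=10, binding_positions=(3, 7))
    return text, manifest


def brute_force_contacts(structure, ligand, cutoff, chain_id=None):
    """Independent all-pairs oracle for binding-residue extraction."""
    if chain_id is None:
        chain_id = ligand.chain_id
    hits = {}
    for pos, res in enumerate(structure.chains[chain_id], start=1):
        best = min(
            float(np.linalg.norm(a.coords - la.coords))
            for a in res.atoms
            for la in ligand.atoms
        )
        if best <= cutoff:
            hits[pos] = best
    return hits


def make_w_ramp_objective(data_seed=23, n_pos=40, n_neg=40, folds=3, cv_seed=0):
    """Objective whose separability is controlled by the window-size gene.

    The data provider scales class separation linearly with w (0 at w=3,
    4 sigma at w=21), so fitness climbs with the w gene.
    """
    from plbind.hyperopt import GeneSpec, Objective, SearchSpace

    space = SearchSpace(
        "svm",
        (
            GeneSpec("C", 0.1, 30.0),
            GeneSpec("sigma", 0.01, 20.0),
            GeneSpec("w", 3, 21, odd=True),
        ),
    )

    def data_for_w(w):
        sep = 4.0 * (w - 3) / 18.0
        data, _ = fx.gen_labeled_features(
            data_seed, n_pos=n_pos, n_neg=n_neg, w=w, separation_sigma=sep
        )
        return data

    return Objective(space, data_for_w, folds=folds, seed=cv_seed)


def pair_count_auc(scores, labels):
    """Exhaustive concordant-pair AUC oracle (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = len(pos) * len(neg)
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / total
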