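import numpy as np
import pytest

from dcmkit.estimation import GDINAEstimator, _group_index
from dcmkit.latent import QMatrix, enumerate_classes

# the published part Q-matrix used across tests (15 items, 9 criteria)
PART_QMATRIX_ROWS = [
    [1, 0, 0, 0, 0, 1, 0, 0, 1],
    [0, 0, 0, 0, 0, 1, 0, 0, 1],
    [0, 0, 1, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 0],
    [1, 0, 0, 0, 1, 0, 0, 0, 0],
    [1, 0, 0, 0, 0, 1, 0, 0, 1],
    [1, 0, 0, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 0, 1, 0, 0, 0, 0],
    [0, 1, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 1],
    [0, 0, 1, 0, 0, 1, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 1, 0, 0, 1],
    [0, 1, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 1],
]


@pytest.fixture(scope="session")
def part_qmatrix() -> QMatrix:
    import warnings

    with warnings.catch_warnings():
        # the 15-item pool leaves two criteria uncovered, by construction
        warnings.simplefilter("ignore")
        return QMatrix(np.array(PART_QMATRIX_ROWS))


def assemble_fitted(q: QMatrix, tables, class_props,
                    structure="fixed") -> GDINAEstimator:
    """Build a 'fitted' estimator directly from known parameters (no EM),
    for oracle tests that need exact endorsement tables."""
    est = GDINAEstimator(q, models="GDINA", structure=structure,
                         fixed_class_props=np.asarray(class_props, float))
    est.q_ = q
    est.space_ = enumerate_classes(q.n_criteria)
    est.assignment_ = ["GDINA"] * q.n_items
    est.group_index_ = _group_index(q, est.space_)
    est.prob_tables_ = [np.asarray(t, dtype=float) for t in tables]
    est.class_props_ = np.asarray(class_props, dtype=float)
    est.loglik_ = 0.0
    est.loglik_path_ = np.zeros(1)
    est.n_iter_ = 0
    est.converged_ = True
    est.warnings_ = []
    est.item_params_ = None
    return est
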