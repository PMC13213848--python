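import numpy as np
import pytest

from raterbench import AssessmentTable, CategorySet


@pytest.fixture
def cats() -> CategorySet:
    return CategorySet()


def random_table(
    rng: np.random.Generator,
    n_subjects: int,
    n_raters: int,
    tie_rate: float = 0.0,
    cats: CategorySet | None = None,
) -> AssessmentTable:
    """Random complete study with an engineered exact-tie rate.

    Truth always contains at least one subject of each binary class; with
    probability ``tie_rate`` a case's top two categories are forced into an
    exact tie.
    """
    cats = cats or CategorySet()
    subjects = [f"s{i:02d}" for i in range(n_subjects)]
    raters = [f"r{j}" for j in range(n_raters)]
    truth = [cats.positive if i % 2 == 0 else cats.negative for i in range(n_subjects)]
    rng.shuffle(truth)
    truth[0], truth[1] = cats.positive, cats.negative
    probs = {}
    for rater in raters:
        mat = rng.dirichlet(np.ones(cats.n), size=n_subjects)
        for i in range(n_subjects):
            if rng.random() < tie_rate:
                order = np.argsort(-mat[i])
                top = mat[i][order[:2]].mean()
                mat[i][order[:2]] = top
                mat[i] /= mat[i].sum()
        probs[rater] = mat
    return AssessmentTable.from_arrays(subjects, raters, truth, probs, cats)


@pytest.fixture
def make_table():
    return random_table
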