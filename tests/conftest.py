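import numpy as np
import pytest

from bcitrack.metrics import TrialCovariance


def make_spd(rng: np.random.Generator, d: int = 4, scale: float = 1.0) -> np.ndarray:
    """Random well-conditioned SPD matrix."""
    a = rng.standard_normal((d, d))
    q, _ = np.linalg.qr(a)
    w = np.exp(scale * rng.standard_normal(d))
    return (q * w) @ q.T


def make_cov_trials(
    rng: np.random.Generator,
    n_per_class: int,
    n_blocks: int = 2,
    d: int = 4,
    spread: float = 0.3,
    separation: float = 1.0,
) -> list[TrialCovariance]:
    """Synthetic covariance-level session: two classes with distinct SPD
    centres, log-normal scatter around each, chronological block order."""
    centres = [np.eye(d), make_spd(rng, d, separation)]
    trials = []
    idx = 0
    for b in range(1, n_blocks + 1):
        labels = rng.permutation([0] * n_per_class + [1] * n_per_class)
        for lab in labels:
            c = centres[lab]
            sq = np.linalg.cholesky(c)
            e = rng.standard_normal((d, d)) * spread
            e = (e + e.T) / 2
            ew, ev = np.linalg.eigh(e)
            pert = (ev * np.exp(ew)) @ ev.T
            mat = sq @ pert @ sq.T
            trials.append(
                TrialCovariance(matrix=(mat + mat.T) / 2, label=int(lab), block=b, index=idx)
            )
            idx += 1
    return trials


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def cov_session(rng) -> list[TrialCovariance]:
    """Two-block, 2x8-trials-per-block covariance session."""
    return make_cov_trials(rng, n_per_class=8, n_blocks=2)
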