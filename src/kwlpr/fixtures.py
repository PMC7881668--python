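"""Seeded synthetic-data generators for end-to-end pipeline testing.

Each generator returns a full :class:`~kwlpr.dataio.Dataset` in the standard
CSV layout (id, split, response, descriptors) together with the noiseless
ground-truth regression function, enabling parameter-recovery tests without
any external data:

* ``sine1d``    — one descriptor, smooth sinusoidal truth plus Gaussian
  noise; the default noise level puts the signal-to-noise ratio at 3:1.
* ``linear1d``  — exact affine truth (noise defaults to 0), the fixture for
  polynomial-reproduction checks.
* ``qsaar2d``   — two correlated Gaussian descriptors emulating a
  lipophilicity/lower-species-potency pair (correlation 0.5 by default, the
  moderate level typical of interspecies toxicity tables), response a smooth
  monotone function of both plus noise.
* ``noise_only`` — response independent of the descriptor; the null fixture
  for Y-scrambling behavior.

Identical spec + seed always reproduce the identical table.  Any change to a
generator must bump :data:`FIXTURE_VERSION`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import Dataset, dataset_from_arrays
from .exceptions import KwlprError

#: bumped whenever any generator's output changes
FIXTURE_VERSION = 1

GENERATORS = ("sine1d", "linear1d", "qsaar2d", "noise_only")

#: sd of sin(x), x ~ U(0, 2*pi); noise at a third of this is SNR 3:1
_SINE_SIGNAL_SD = np.sqrt(0.5)

_DEFAULT_NOISE = {
    "sine1d": _SINE_SIGNAL_SD / 3.0,
    "linear1d": 0.0,
    "qsaar2d": 0.6,
    "noise_only": 1.0,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic table."""

    generator: str
    n_train: int = 60
    n_valid: int = 0
    noise_sd: float | None = None  # None -> generator default
    descriptor_correlation: float = 0.5  # qsaar2d only
    seed: int = 1

    def __post_init__(self):
        if self.generator not in GENERATORS:
            raise KwlprError(f"unknown generator {self.generator!r}; choose from {GENERATORS}")
        if self.n_train < 3 or self.n_valid < 0:
            raise KwlprError("need n_train >= 3 and n_valid >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise KwlprError("noise_sd must be >= 0")
        if not -1.0 < self.descriptor_correlation < 1.0:
            raise KwlprError("descriptor_correlation must lie in (-1, 1)")

    @property
    def n(self) -> int:
        return self.n_train + self.n_valid

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return _DEFAULT_NOISE[self.generator]


def generate(spec: FixtureSpec):
    """Build the Dataset for ``spec``; returns ``(dataset, truth)`` where
    ``truth(X)`` evaluates the noiseless regression function row-wise."""
    rng = np.random.default_rng(spec.seed)
    n, sd = spec.n, spec.effective_noise_sd

    if spec.generator == "sine1d":
        X = rng.uniform(0.0, 2.0 * np.pi, size=(n, 1))
        truth = lambda X: np.sin(np.asarray(X, float)[:, 0])  # noqa: E731
        names = ["x"]
    elif spec.generator == "linear1d":
        X = rng.uniform(-1.0, 3.0, size=(n, 1))
        truth = lambda X: 2.0 * np.asarray(X, float)[:, 0] + 1.0  # noqa: E731
        names = ["x"]
    elif spec.generator == "qsaar2d":
        rho = spec.descriptor_correlation
        mean = np.array([2.5, 1.5])
        sds = np.array([1.5, 1.2])
        cov = np.array(
            [[sds[0] ** 2, rho * sds[0] * sds[1]],
             [rho * sds[0] * sds[1], sds[1] ** 2]]
        )
        X = rng.multivariate_normal(mean, cov, size=n)

        def truth(X):
            X = np.asarray(X, float)
            return (0.27 + 0.17 * X[:, 0] + 0.67 * X[:, 1]
                    + 1.2 * np.tanh(X[:, 0] - 2.5))

        names = ["logp", "pec50_lower_species"]
    else:  # noise_only
        X = rng.normal(0.0, 1.0, size=(n, 1))
        truth = lambda X: np.zeros(np.asarray(X, float).shape[0])  # noqa: E731
        names = ["x"]

    y = truth(X) + rng.normal(0.0, sd, size=n) if sd > 0 else truth(X)
    ids = [f"C{i + 1:04d}" for i in range(n)]
    split = ["train"] * spec.n_train + ["validation"] * spec.n_valid
    ds = dataset_from_arrays(ids, split, y, X, names)
    return ds, truth
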