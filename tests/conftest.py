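"""Shared fixtures: scripted random streams and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import squirrelselect as ss


class ScriptedRNG:
    """Random-stream stand-in whose draws are forced by the test.

    ``uniform`` pops unit draws from a queue and maps them onto
    ``[low, high)``; ``integers`` and ``standard_normal`` pop from their own
    queues; ``permutation`` returns its argument unchanged (identity order).
    Exhausting a queue raises, which doubles as a draw-count assertion.
    """

    def __init__(self, uniforms=(), ints=(), normals=()):
        self._uniforms = list(uniforms)
        self._ints = list(ints)
        self._normals = list(normals)

    def _pop_uniforms(self, n):
        if len(self._uniforms) < n:
            raise AssertionError(f"scripted stream exhausted: wanted {n} more uniform draw(s)")
        out, self._uniforms = self._uniforms[:n], self._uniforms[n:]
        return np.asarray(out, dtype=float)

    def uniform(self, low=0.0, high=1.0, size=None):
        low = np.asarray(low, dtype=float)
        high = np.asarray(high, dtype=float)
        if size is None and (low.ndim or high.ndim):
            size = np.broadcast_shapes(low.shape, high.shape)
        if size is None:
            return float(low + self._pop_uniforms(1)[0] * (high - low))
        shape = (size,) if isinstance(size, int) else tuple(size)
        u = self._pop_uniforms(int(np.prod(shape))).reshape(shape)
        return low + u * (high - low)

    def integers(self, low, high=None):
        if not self._ints:
            raise AssertionError("scripted stream exhausted: wanted an integer draw")
        return self._ints.pop(0)

    def permutation(self, x):
        return np.asarray(x)

    def standard_normal(self, size=None):
        n = 1 if size is None else int(np.prod((size,) if isinstance(size, int) else size))
        if len(self._normals) < n:
            raise AssertionError("scripted stream exhausted: wanted more normal draws")
        out, self._normals = self._normals[:n], self._normals[n:]
        arr = np.asarray(out, dtype=float)
        return float(arr[0]) if size is None else arr.reshape(size)


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-condition cohort (n=200, 30 features, 5 informative)."""
    return ss.generate(ss.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def separable_cohort():
    """Strongly separable cohort (effect size 3.0)."""
    return ss.generate(ss.SyntheticSpec(effect_size=3.0, seed=1))
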