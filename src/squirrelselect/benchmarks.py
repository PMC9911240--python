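"""Named continuous benchmark objectives for exercising the optimizer."""

from __future__ import annotations

import numpy as np

__all__ = ["sphere", "rastrigin", "ackley", "rosenbrock", "BENCHMARKS", "get_benchmark"]


def sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x, dtype=float) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def ackley(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    d = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


#: name -> (objective, conventional lower bound, upper bound)
BENCHMARKS = {
    "sphere": (sphere, -5.0, 5.0),
    "rastrigin": (rastrigin, -5.12, 5.12),
    "ackley": (ackley, -32.768, 32.768),
    "rosenbrock": (rosenbrock, -2.048, 2.048),
}


def get_benchmark(name: str):
    """Look up ``(objective, lower, upper)`` by name; raise on unknown names."""
    try:
        return BENCHMARKS[name]
    except KeyError:
        raise KeyError(
            f"unknown benchmark {name!r}; available: {sorted(BENCHMARKS)}"
        ) from None
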