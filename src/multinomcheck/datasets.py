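"""Packaged example datasets and the synthetic count generator.

The four bundled count vectors are the worked examples used throughout the
documentation and tests: two trine-measurement experiments (qubit state
estimation), the CCR-5 genotype sample (Hardy-Weinberg checking) and a fly
species-abundance table (ordered probabilities).  ``simulate_counts`` wraps
the generate-theta-then-counts scheme used everywhere a prior predictive is
sampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import CellCounts, ProbabilityVector, RngLike, ensure_rng

__all__ = ["NamedDataset", "load_dataset", "list_datasets", "simulate_counts"]


@dataclass(frozen=True)
class NamedDataset:
    name: str
    counts: CellCounts
    labels: tuple
    n: int
    model: str
    description: str


def _metadata() -> dict:
    with resources.files(__package__).joinpath("data/datasets.json").open() as fh:
        return json.load(fh)


def list_datasets() -> list[str]:
    return sorted(_metadata())


def load_dataset(name: str) -> NamedDataset:
    """Load one of the packaged datasets by name."""
    meta = _metadata()
    if name not in meta:
        raise ValueError(f"unknown dataset {name!r}; choose from {sorted(meta)}")
    info = meta[name]
    with resources.files(__package__).joinpath(f"data/{info['file']}").open() as fh:
        df = pd.read_csv(fh)
    counts = CellCounts(df["count"].to_numpy())
    if counts.n != info["n"]:
        raise RuntimeError(
            f"packaged dataset {name} is corrupt: n = {counts.n} != {info['n']}")
    return NamedDataset(name=name, counts=counts,
                        labels=tuple(df["cell"]), n=info["n"],
                        model=info["model"], description=info["description"])


def simulate_counts(theta_or_sampler, n: int, reps: int = 1,
                    rng: RngLike = None) -> list[CellCounts]:
    """Draw ``reps`` count vectors of size ``n``.

    ``theta_or_sampler`` is either a fixed simplex point (every replicate
    uses the same theta) or a callable ``sampler(size, rng) -> (reps, k+1)``
    array of simplex points, in which case a fresh theta is drawn for each
    replicate -- the prior-predictive scheme.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if reps < 0:
        raise ValueError("reps must be >= 0")
    if reps == 0:
        return []
    gen = ensure_rng(rng)
    if callable(theta_or_sampler):
        thetas = np.asarray(theta_or_sampler(reps, gen), dtype=float)
    else:
        p = np.asarray(ProbabilityVector(theta_or_sampler))
        thetas = np.broadcast_to(p, (reps, p.size))
    draws = gen.multinomial(n, thetas)
    return [CellCounts(row) for row in draws]
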