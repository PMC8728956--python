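"""High-level simulation driver: volume building, worker split, merge.

A run of N photons is divided as evenly as possible across W logical
workers (counts differ by at most one).  Photon *i* always draws from RNG
stream ``(seed, i)`` no matter which worker executes it, so worker count
never changes physics — only the order in which voxel bins are summed.
Workers execute sequentially in-process; the split/merge path is the same
one a distributed deployment would use.
"""

from __future__ import annotations

import numpy as np

from . import shapes as shapes_mod
from .kernel import (
    DEFAULT_RR_SURVIVE,
    DEFAULT_RR_THRESHOLD,
    transport_run,
)
from .output import SimResult, merge_results, normalize_fluence
from .scene import SimConfig

__all__ = ["build_volume", "run_simulation", "split_photons"]


def build_volume(config: SimConfig) -> np.ndarray:
    """Label (or per-voxel property) volume for a parsed config."""
    if config.domain.volume is not None:
        return config.domain.volume
    vol = shapes_mod.rasterize(config.shapes, dim=config.domain.dim)
    if vol.shape != tuple(config.domain.dim):
        raise ValueError(
            f"Shapes grid {vol.shape} disagrees with Domain.Dim {config.domain.dim}"
        )
    if vol.max(initial=0) >= len(config.domain.media):
        raise ValueError("rasterized label exceeds the defined Media list")
    return vol


def split_photons(n: int, workers: int) -> list[int]:
    """Even split: e.g. 10 photons over 4 workers -> [3, 3, 2, 2]."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    base, extra = divmod(n, workers)
    return [base + (1 if i < extra else 0) for i in range(workers)]


def run_simulation(
    config: SimConfig,
    *,
    photons: int | None = None,
    seed: int | None = None,
    workers: int = 1,
    rr_threshold: float = DEFAULT_RR_THRESHOLD,
    rr_survive: float = DEFAULT_RR_SURVIVE,
    normalize: bool | None = None,
) -> SimResult:
    """Run the full simulation and return a (normalized) :class:`SimResult`."""
    n = config.session.photons if photons is None else int(photons)
    seed = config.session.rng_seed if seed is None else int(seed)
    volume = build_volume(config)
    counts = split_photons(n, workers)
    parts = []
    offset = 0
    for count in counts:
        if count == 0:
            continue
        raw, detected, acct = transport_run(
            config,
            volume,
            photon_offset=offset,
            n_photons=count,
            seed=seed,
            rr_threshold=rr_threshold,
            rr_survive=rr_survive,
        )
        parts.append(
            SimResult(
                config=config,
                volume=volume,
                raw=raw,
                detected=detected,
                accounting=acct,
                seed=seed,
                worker_photons=[count],
            )
        )
        offset += count
    result = parts[0] if len(parts) == 1 else merge_results(parts)
    do_norm = config.session.do_normalize if normalize is None else normalize
    if do_norm:
        result = normalize_fluence(result)
    return result
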