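"""Run configuration: one YAML file drives every CLI stage.

A run is fully reproducible from (inputs, config, seed): the same config and
seed produce bitwise-identical map sets and tables.  Each stage logs its
input hashes, parameters, seed and wall time.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "stage_logging"]

logger = logging.getLogger("matnets")


@dataclass
class RunConfig:
    """Named parameters for every pipeline stage, with sane toy-scale defaults.

    ``paths`` holds stage inputs/outputs (mask, cohort, series_dir, dense,
    maps...); each stage section is a plain dict merged over these defaults.
    """

    paths: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    smooth: dict = field(default_factory=dict)
    connectome: dict = field(default_factory=dict)
    matnets: dict = field(default_factory=dict)
    gica: dict = field(default_factory=dict)
    dualreg: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    hubs: dict = field(default_factory=dict)
    univariate: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)
    seed: int = 0

    _DEFAULTS = {
        "simulate": dict(n_subjects=60, n_timepoints=100, n_networks=5,
                         noise_sd=0.5, coupling_slope_per_week=0.045,
                         smear_signal=False, bilateral=True),
        "smooth": dict(fwhm_mm=3.0),
        "connectome": dict(fisher_z=False),
        "matnets": dict(m_components=25, r_keep=None, n_blocks=200),
        "gica": dict(m_components=25, r_keep=None),
        "dualreg": dict(normalise_timecourses=True),
        "profiles": dict(affinity="positive", n_dims=3),
        "hubs": dict(),
        "univariate": dict(n_parcels=30, z_pos=3.0),
        "coupling": dict(z_thresh=5.0, orders=[1, 2, 3], alpha=0.05),
    }

    def stage(self, name: str) -> dict:
        merged = dict(self._DEFAULTS.get(name, {}))
        merged.update(getattr(self, name))
        return merged


def load_config(path) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = {k: raw.pop(k) for k in list(raw) if k in RunConfig.__dataclass_fields__}
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(**known)


def _hash_obj(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
    elif isinstance(obj, (str, Path)) and Path(obj).is_file():
        h.update(Path(obj).read_bytes())
    else:
        h.update(repr(obj).encode())
    return h.hexdigest()[:12]


@contextmanager
def stage_logging(stage: str, seed: int, params: dict, inputs: dict | None = None):
    """Log (input hashes, params, seed, wall time) around a pipeline stage."""
    hashes = {k: _hash_obj(v) for k, v in (inputs or {}).items()}
    logger.info("stage=%s seed=%d params=%s inputs=%s", stage, seed, params, hashes)
    t0 = time.perf_counter()
    yield
    logger.info("stage=%s done in %.2fs", stage, time.perf_counter() - t0)
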