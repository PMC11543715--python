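"""Shared fixtures.

The expensive fixture is ``experiment``: the full factorial simulation
(8 design cells, TEACH sleep variant) plus the far/related cell under
the three alternative sleep variants, for 20 seeded runs.  It is
computed once per session and shared by the statistical and acceptance
tests; per-run condition cells branch from cached network states where
the pipeline prefix is shared, which is exactly equivalent to running
each cell from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from teach.config import RunConfig
from teach.design import ConditionSpec, ScheduleParams
from teach.model import TeachConfig
from teach.protocol import all_cells, run_cell

N_RUNS = 20


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


@pytest.fixture
def tiny_cfg():
    """Miniature architecture for fast structural/dynamics tests."""
    return TeachConfig(
        dg_shape=(10, 10),
        ca3_shape=(8, 8),
        ca1_pool_shape=(5, 5),
        cycles_per_quarter=4,
        codec_epochs=1,
    )


@pytest.fixture
def tiny_sched():
    return ScheduleParams(
        pretrain_epochs=2,
        study_epochs=1,
        rp_epochs=1,
        sleep_base_epochs=1,
        sleep_extra_epochs=1,
    )


def _run_full_experiment(n_runs: int = N_RUNS) -> dict:
    cfg = RunConfig()  # standard defaults
    net_cfg, sched = cfg.network, cfg.schedule
    teach_frames, variant_frames = [], []
    variant_cells = [
        ConditionSpec("far", "related", "sleep", v)
        for v in ("AddRP", "PriWeak", "All")
    ]
    for run in range(1, n_runs + 1):
        cache: dict = {}
        for cond in all_cells("TEACH") + variant_cells:
            result = run_cell(
                net_cfg,
                sched,
                cond,
                run,
                cfg.master_seed,
                n_scenes=cfg.n_scenes,
                pct_active=cfg.pct_active,
                active_threshold=cfg.active_threshold,
                cache=cache,
            )
            frame = result.to_frame()
            if cond.sleep_variant == "TEACH":
                teach_frames.append(frame)
            else:
                variant_frames.append(frame)
    return {
        "teach": pd.concat(teach_frames, ignore_index=True),
        "variants": pd.concat(variant_frames, ignore_index=True),
        "config": cfg,
    }


@pytest.fixture(scope="session")
def experiment():
    return _run_full_experiment()
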