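"""Shared fixtures: the desk-scale simulation study used across the suite.

The study fixture trains the full pipeline once per session on the
generator defaults (10 modules of 30 genes, two with a class shift d = 2,
gene-factor correlation 0.85, 150 samples per class) and evaluates it on a
large held-out draw from the same ground truth, both same-platform and
after a synthetic platform change.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from modulebayes import (
    RunConfig,
    generate_expression,
    generate_from_truth,
    performance,
    platform_transform,
    predict,
    train_from_expression,
)

logging.getLogger("modulebayes").setLevel(logging.ERROR)
logging.getLogger("py.warnings").setLevel(logging.ERROR)

STUDY_SEED = 0
HELDOUT_SEED = 7919
PLATFORM_SEED = 15881


@pytest.fixture(scope="session")
def study():
    """Full pipeline trained on the default synthetic study conditions."""
    x, labels, truth = generate_expression(seed=STUDY_SEED)
    cfg = RunConfig(seed=STUDY_SEED)
    cfg.bn.R = 100
    ensemble, modules, eigen = train_from_expression(x, labels, cfg)

    x_test, y_test = generate_from_truth(truth, 1000, 1000, seed=HELDOUT_SEED,
                                         prefix="t")
    res_same = predict(ensemble, x_test)
    perf_same = performance(
        res_same["majority"].to_numpy(), y_test.to_numpy(),
        scores=res_same["posterior"].to_numpy(),
    )
    x_cross = platform_transform(x_test, seed=PLATFORM_SEED,
                                 noise_sd=0.5, dropout=0.1)
    res_cross = predict(ensemble, x_cross)
    perf_cross = performance(
        res_cross["majority"].to_numpy(), y_test.to_numpy(),
        scores=res_cross["posterior"].to_numpy(),
    )
    return {
        "x": x, "labels": labels, "truth": truth,
        "config": cfg, "ensemble": ensemble, "modules": modules,
        "eigen": eigen, "x_test": x_test, "y_test": y_test,
        "perf_same": perf_same, "perf_cross": perf_cross,
    }


def detected_name_of_planted(study_dict, planted_module: int) -> str | None:
    """Map a planted module index to the detected module column name."""
    modules = study_dict["modules"]
    truth = study_dict["truth"]
    for m in modules.module_ids:
        genes = modules.genes_in(m)
        if int(truth.membership.loc[genes].mode()[0]) == planted_module:
            return f"M{m}"
    return None
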