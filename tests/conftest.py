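import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import configuration, settings

from mrmediate.data import HarmonizedPanel, SummaryStats

# property tests are derandomized; keep all hypothesis caches out of the tree
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))
settings.register_profile("default", database=None, deadline=None)
settings.load_profile("default")


def make_panel(bx, by, sy, sx=None, bm=None, sm=None,
               exposure="x", outcome="y", mediator=None,
               stratum="combined") -> HarmonizedPanel:
    """Hand-built harmonized panel for estimator tests."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 1e-8) if sx is None else np.asarray(sx, dtype=float)
    idx = pd.Index([f"rs{i + 1}" for i in range(len(bx))], name="rsid")
    beta = {exposure: bx, outcome: by}
    se = {exposure: sx, outcome: sy}
    if bm is not None:
        mediator = mediator or "m"
        beta[mediator] = np.asarray(bm, dtype=float)
        se[mediator] = (np.full_like(bx, 1e-8) if sm is None
                        else np.asarray(sm, dtype=float))
    return HarmonizedPanel(
        beta=pd.DataFrame(beta, index=idx), se=pd.DataFrame(se, index=idx),
        exposure=exposure, outcome=outcome, mediator=mediator, stratum=stratum,
    )


def make_sumstats(trait, rows, stratum="combined") -> SummaryStats:
    """rows: list of dicts with any of the canonical columns; the rest
    filled with innocuous defaults."""
    defaults = {"chrom": "1", "pos": 1000, "ea": "A", "oa": "G",
                "eaf": 0.3, "beta": 0.1, "se": 0.01, "pval": 1e-9, "n": 10000}
    table = pd.DataFrame([{**defaults, **r} for r in rows])
    return SummaryStats(trait, stratum, table)


@pytest.fixture
def three_snp_panel():
    """IVW worked instance: beta 390/1400, Q = 19/14."""
    return make_panel(bx=[0.1, 0.2, 0.3], by=[0.02, 0.05, 0.09],
                      sy=[0.01, 0.01, 0.01])
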