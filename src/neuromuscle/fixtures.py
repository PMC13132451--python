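"""Deterministic demo-input generation.

Everything the test suite and examples consume is generated here from
code: the shipped presets and correlation tables are copied out, pool
specifications for 10- and 100-cell motor-unit pools are written, and
(optionally) one drive signal per protocol family is exported as CSV.
The same seed always produces byte-identical files.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from . import config
from . import inverse as inv
from . import io as nio
from . import protocols as pr
from .signals import gen_spike_train

#: Rank-distribution exponents spanning S-dominant through F-dominant
#: pool organizations (applied to the R_N cell indicator).
ORGANIZATION_GAMMAS = {"s_dominant": 0.25, "s_lean": 0.5, "linear": 1.0,
                       "f_lean": 2.0, "f_dominant": 4.0}

#: Default cell-indicator ranges.
RN_RANGE = (1.4, 2.8)      # MOhm
P05_RANGE = (0.15, 0.6)    # N


def pool_spec_table(n: int) -> pd.DataFrame:
    """Cell-indicator values for an n-cell MU pool under each of the five
    organization shapes."""
    rows = {}
    for name, gamma in ORGANIZATION_GAMMAS.items():
        rows[name] = inv.ci_rank_distribution(n, *RN_RANGE, gamma)
    return pd.DataFrame(rows)


def generate_fixtures(outdir: pathlib.Path, seed: int = 0,
                      demo: bool = False) -> list[pathlib.Path]:
    """Write presets, correlation tables, pool specs, and optional demo
    drive signals; returns the created paths."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    for kind, names in (("MN", nio.MN_PRESETS), ("MT", nio.MT_PRESETS)):
        for name in names:
            pf = nio.load_preset_file(kind, name)
            p = outdir / f"{kind}_{name}.csv"
            nio.write_parameter_csv(pf, p)
            paths.append(p)

    for kind in ("MN", "MT", "MU"):
        cs = inv.load_default_correlations(kind)
        p = outdir / f"correlations_{kind.lower()}.csv"
        cs.to_csv(p)
        paths.append(p)

    for n in (10, 100):
        p = outdir / f"mu_pool_spec_{n}.csv"
        pool_spec_table(n).to_csv(p, index=False)
        paths.append(p)

    if demo:
        dt = config.DT_MS
        sigs = {
            "i_soma_triangular": pr.triangular_current(T_ms=4000.0),
            "i_soma_bistability": pr.bistability_current(T_ms=4000.0,
                                                         delay_ms=3000.0),
        }
        sigs.update({f"x_m_{k}": v for k, v in pr.length_battery(dt).items()})
        for name, s in sigs.items():
            p = outdir / f"signal_{name}.csv"
            s.to_csv(p)
            paths.append(p)
        p = outdir / "spike_train_40hz.csv"
        gen_spike_train(40.0, 0.0, 1000.0).to_csv(p)
        paths.append(p)
        for i, scheme in enumerate(("constant_inhibition", "balanced",
                                    "push_pull")):
            ds = pr.pool_synaptic_drives(1, scheme, T_ms=2000.0,
                                         seed=seed + i)
            p = outdir / f"drive_{scheme}.csv"
            d = ds.drives[0].drive
            pd.DataFrame({"time_ms": d.g_e.times, "g_e": d.g_e.values,
                          "g_i": d.g_i.values}).to_csv(p, index=False)
            paths.append(p)
    return paths
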