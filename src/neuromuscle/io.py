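"""Parameter-file readers/writers and shipped presets.

A parameter CSV has one row per named parameter with columns
``cell_kind,preset,parameter,group,unit,value`` (comma-separated, UTF-8,
header row, '.' decimal).  ``group`` is RMP for the cell-varying (range)
parameters and CMP for the population constants.  The schema is strict:
every parameter of the kind must appear exactly once with the expected
unit, so a file is a complete, self-describing model specification.

Shipped presets (representative adult-cat values calibrated for this
package's kinetics; see docs/methods.md):

- motoneuron: ``FR`` (fatigue-resistant, the reference bistable cell),
  ``S`` (slow, high input resistance, long AHP), ``FF`` (fast fatigable,
  low input resistance, short AHP)
- muscle-tendon: ``SOL`` (slow, soleus-like), ``MG`` (fast, medial
  gastrocnemius-like)
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .motoneuron import MotoneuronCMP, MotoneuronRMP
from .muscle_tendon import MuscleTendonCMP, MuscleTendonRMP

_MN_UNITS = {
    "g_m_s": "mS/cm2", "g_m_d": "mS/cm2", "g_c": "mS/cm2",
    "c_m_s": "uF/cm2", "c_m_d": "uF/cm2", "g_naf_s": "mS/cm2",
    "f_s": "1", "g_cal_d": "mS/cm2", "g_kca_d": "mS/cm2", "s_nm": "1",
    "d_path": "mm",
    "e_leak": "mV", "e_na": "mV", "e_k": "mV", "e_ca_d": "mV",
    "ca_out": "conc", "g_kdr_s": "mS/cm2", "g_kca_s": "mS/cm2",
    "g_nap_s": "mS/cm2", "g_can_s": "mS/cm2", "area_s": "cm2",
    "area_d": "cm2", "alpha_ca": "conc/(uA/cm2)/ms", "k_ca": "1/ms",
    "f_d": "1", "kd_kca": "conc", "ca_rest": "conc",
    "vh_naf_m": "mV", "k_naf_m": "mV", "vh_naf_h": "mV", "k_naf_h": "mV",
    "vh_kdr": "mV", "k_kdr": "mV", "vh_can_m": "mV", "k_can_m": "mV",
    "vh_can_h": "mV", "k_can_h": "mV", "tau_can_m": "ms", "tau_can_h": "ms",
    "vh_nap": "mV", "k_nap": "mV", "vh_cal": "mV", "k_cal": "mV",
    "tau_cal": "ms", "dpath_slope_mv_per_mm": "mV/mm", "dpath_ref_mm": "mm",
}

_MT_UNITS = {
    "tau_1": "ms", "tau_2": "ms", "phi_1": "1/mm", "phi_3": "1/mm",
    "c1i": "conc", "c1n1": "conc", "c1n4": "ms",
    "c2i": "1", "c2n1": "1", "c2n4": "ms", "alpha_i": "1",
    "beta": "1/mm", "gamma": "s/mm", "p0_5": "N", "g_1": "mm", "g_2": "mm",
    "a_0": "1", "b_0": "mm/s", "c_0": "mm/s", "d_0": "1", "k_se": "N/mm",
    "a_muap": "mV", "l_muap": "ms",
    "x_half": "mm", "tau_fluct": "ms", "v_cap": "mm/s", "ca_sat": "conc",
}

_KINDS = {
    "MN": (MotoneuronRMP, MotoneuronCMP, _MN_UNITS),
    "MT": (MuscleTendonRMP, MuscleTendonCMP, _MT_UNITS),
}


@dataclass
class ParameterFile:
    """Validated parameter table for one preset of one cell kind."""

    cell_kind: str
    preset: str
    table: pd.DataFrame  # columns: parameter, group, unit, value

    def to_model(self):
        """Instantiate (RMP, CMP) dataclasses from the table."""
        rmp_cls, cmp_cls, _ = _KINDS[self.cell_kind]
        vals = dict(zip(self.table.parameter, self.table.value))
        rmp = rmp_cls(**{f.name: vals[f.name]
                         for f in dataclasses.fields(rmp_cls)})
        cmp = cmp_cls(**{f.name: vals[f.name]
                         for f in dataclasses.fields(cmp_cls)})
        rmp.validate()
        if hasattr(cmp, "validate"):
            cmp.validate()
        return rmp, cmp


def parameter_file_from_model(cell_kind: str, preset: str, rmp,
                              cmp) -> ParameterFile:
    rmp_cls, cmp_cls, units = _KINDS[cell_kind]
    rows = []
    for group, obj in (("RMP", rmp), ("CMP", cmp)):
        for f in dataclasses.fields(obj):
            rows.append((f.name, group, units[f.name],
                         float(getattr(obj, f.name))))
    return ParameterFile(cell_kind, preset,
                         pd.DataFrame(rows, columns=["parameter", "group",
                                                     "unit", "value"]))


def _validate(pf: ParameterFile) -> None:
    if pf.cell_kind not in _KINDS:
        raise ValueError(f"unknown cell kind {pf.cell_kind!r}")
    rmp_cls, cmp_cls, units = _KINDS[pf.cell_kind]
    expected = {f.name: "RMP" for f in dataclasses.fields(rmp_cls)}
    expected.update({f.name: "CMP" for f in dataclasses.fields(cmp_cls)})
    seen = list(pf.table.parameter)
    dup = {p for p in seen if seen.count(p) > 1}
    if dup:
        raise ValueError(f"duplicate parameters: {sorted(dup)}")
    missing = sorted(set(expected) - set(seen))
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    unknown = sorted(set(seen) - set(expected))
    if unknown:
        raise ValueError(f"unknown parameters: {unknown}")
    for _, row in pf.table.iterrows():
        if row.group != expected[row.parameter]:
            raise ValueError(f"parameter {row.parameter!r}: group "
                             f"{row.group!r}, expected {expected[row.parameter]!r}")
        if row.unit != units[row.parameter]:
            raise ValueError(f"parameter {row.parameter!r}: unit {row.unit!r},"
                             f" expected {units[row.parameter]!r}")


def write_parameter_csv(pf: ParameterFile, path) -> None:
    _validate(pf)
    out = pf.table.copy()
    out.insert(0, "preset", pf.preset)
    out.insert(0, "cell_kind", pf.cell_kind)
    out.to_csv(path, index=False)


def read_parameter_csv(path) -> ParameterFile:
    df = pd.read_csv(path)
    need = {"cell_kind", "preset", "parameter", "group", "unit", "value"}
    if set(df.columns) != need:
        raise ValueError(f"parameter CSV must have columns {sorted(need)}")
    kinds = df.cell_kind.unique()
    presets = df.preset.unique()
    if len(kinds) != 1 or len(presets) != 1:
        raise ValueError("parameter CSV must describe a single preset")
    pf = ParameterFile(str(kinds[0]), str(presets[0]),
                       df[["parameter", "group", "unit", "value"]]
                       .reset_index(drop=True))
    _validate(pf)
    return pf


# ---------------------------------------------------------------------------
# shipped presets


def _data_path(name: str):
    return importlib.resources.files("neuromuscle.data") / name

MN_PRESETS = ("FR", "S", "FF")
MT_PRESETS = ("SOL", "MG")


def load_preset(cell_kind: str, preset: str):
    """Load a shipped preset; returns (rmp, cmp)."""
    fname = f"{cell_kind}_{preset}.csv"
    with importlib.resources.as_file(_data_path(fname)) as p:
        return read_parameter_csv(p).to_model()


def load_preset_file(cell_kind: str, preset: str) -> ParameterFile:
    fname = f"{cell_kind}_{preset}.csv"
    with importlib.resources.as_file(_data_path(fname)) as p:
        return read_parameter_csv(p)
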