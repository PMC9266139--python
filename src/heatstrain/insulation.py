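"""Clothing insulation from thermal-manikin records (serial model).

A heated manikin held at constant surface temperature measures, per body
segment, the surface temperature T_si, the heat loss H_ci and the surface
area a_i, once nude and once clothed.  Local resistance is
(T_si - Ta) * a_i / H_ci; the serial model sums local resistances with the
nude area factors f_i = a_i / A.  The clothed run gives the total
insulation I_t, the nude run the boundary-air insulation I_a, and the
basic (intrinsic) insulation follows as

    I_cl = I_t - I_a / f_cl

with f_cl the clothing area factor.  A historical variant
(I_t - I_a) / f_cl is available behind a flag for comparison; it is not
consistent with standard whole-body results and is off by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CLO

__all__ = ["steady_state_average", "total_insulation", "basic_insulation",
           "SerialInsulationModel", "InsulationResults", "MissingSegmentsError"]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ("segment", "condition", "run", "minute",
                  "tsurf_c", "heat_w", "area_m2")


class MissingSegmentsError(ValueError):
    """A condition lacks records for segments present in the other."""


def _check_records(df: pd.DataFrame):
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table lacks columns: {missing}")
    bad = set(df["condition"].unique()) - {"nude", "clothed"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")


def steady_state_average(records: pd.DataFrame, window_min: int = 30
                         ) -> pd.DataFrame:
    """Time-average the last ``window_min`` minutes per segment and run,
    then average across runs.

    Returns one row per (condition, segment) with mean tsurf_c, heat_w and
    area_m2 plus the standard error of the local resistance implied by the
    minute-to-minute spread.
    """
    _check_records(records)
    out = []
    for (cond, seg, run), g in records.groupby(["condition", "segment", "run"]):
        if g["minute"].nunique() < window_min:
            raise ValueError(
                f"segment {seg!r} ({cond}, run {run}) has "
                f"{g['minute'].nunique()} min of records, need {window_min}")
        tail = g[g["minute"] > g["minute"].max() - window_min]
        out.append(dict(condition=cond, segment=seg, run=run,
                        tsurf_c=tail["tsurf_c"].mean(),
                        heat_w=tail["heat_w"].mean(),
                        area_m2=tail["area_m2"].mean(),
                        heat_se_w=tail["heat_w"].std(ddof=1)
                        / np.sqrt(len(tail)) if len(tail) > 1 else 0.0))
    per_run = pd.DataFrame(out)
    agg = (per_run.groupby(["condition", "segment"], as_index=False)
           .agg(tsurf_c=("tsurf_c", "mean"), heat_w=("heat_w", "mean"),
                area_m2=("area_m2", "mean"), heat_se_w=("heat_se_w",
                lambda s: np.sqrt(np.mean(np.square(s)) / len(s)))))
    return agg


def total_insulation(averaged: pd.DataFrame, ta_c: float,
                     condition: str) -> float:
    """Serial-model whole-body insulation for one condition, m2K/W.

    I = sum_i f_i * (T_si - Ta) * a_i / H_ci with f_i = a_i / A computed
    over the segments present.  ``condition='nude'`` yields the air-layer
    insulation, ``'clothed'`` the total insulation.
    """
    sub = averaged[averaged["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no records for condition {condition!r}")
    if (sub["tsurf_c"] <= ta_c).any():
        bad = sub.loc[sub["tsurf_c"] <= ta_c, "segment"].tolist()
        raise ValueError(
            f"surface temperature not above air temperature for {bad}; "
            "a heated manikin must be warmer than the chamber")
    f = sub["area_m2"] / sub["area_m2"].sum()
    r_local = (sub["tsurf_c"] - ta_c) * sub["area_m2"] / sub["heat_w"]
    return float((f * r_local).sum())


def basic_insulation(i_t: float, i_a: float, f_cl: float,
                     printed_form: bool = False) -> float:
    """Basic clothing insulation from total and air insulation.

    Standard serial-model correction: I_cl = I_t - I_a / f_cl.  Units
    follow the inputs (clo in, clo out).  With ``printed_form=True`` the
    variant (I_t - I_a) / f_cl is computed instead.  A negative result is
    returned with a warning; it signals inconsistent inputs.
    """
    if f_cl < 1.0:
        raise ValueError(f"clothing area factor must be >= 1, got {f_cl}")
    i_cl = (i_t - i_a) / f_cl if printed_form else i_t - i_a / f_cl
    if i_cl < 0:
        log.warning("basic insulation is negative (%.4f); inputs are "
                    "inconsistent", i_cl)
    return i_cl


class SerialInsulationModel:
    """Serial-model insulation estimator over a manikin record table.

    Parameters
    ----------
    records : long-format table with columns segment, condition
        (nude/clothed), run, minute, tsurf_c, heat_w, area_m2.
    ta_c : chamber air temperature, degC.
    f_cl : clothing area factor (measured or taken from garment tables).
    window_min : steady-state averaging window, min.
    printed_form : use the historical (I_t - I_a)/f_cl variant.
    """

    def __init__(self, records: pd.DataFrame, ta_c: float, f_cl: float = 1.36,
                 window_min: int = 30, printed_form: bool = False):
        _check_records(records)
        self.records = records
        self.ta_c = float(ta_c)
        self.f_cl = float(f_cl)
        self.window_min = int(window_min)
        self.printed_form = bool(printed_form)

    def fit(self) -> "InsulationResults":
        avg = steady_state_average(self.records, self.window_min)
        nude = set(avg.loc[avg.condition == "nude", "segment"])
        clothed = set(avg.loc[avg.condition == "clothed", "segment"])
        if not nude or not clothed:
            present = ([] if not nude else ["nude"]) + ([] if not clothed else ["clothed"])
            raise MissingSegmentsError(
                "need both nude and clothed records; only have: "
                + (", ".join(present) or "none"))
        common = nude & clothed
        dropped = sorted((nude | clothed) - common)
        if dropped:
            log.info("segments without both conditions dropped; area "
                     "factors renormalised over the rest: %s", dropped)
        if not common:
            raise MissingSegmentsError("no segment has both nude and clothed records")
        avg = avg[avg["segment"].isin(common)].reset_index(drop=True)

        i_t = total_insulation(avg, self.ta_c, "clothed")
        i_a = total_insulation(avg, self.ta_c, "nude")
        i_cl = basic_insulation(i_t, i_a, self.f_cl, self.printed_form)

        # delta-method standard errors from the minute-to-minute spread
        ses = {}
        for cond, name in (("clothed", "i_t"), ("nude", "i_a")):
            sub = avg[avg["condition"] == cond]
            f = (sub["area_m2"] / sub["area_m2"].sum()).to_numpy()
            dt = (sub["tsurf_c"] - self.ta_c).to_numpy()
            var_r = (dt * sub["area_m2"].to_numpy()
                     / sub["heat_w"].to_numpy() ** 2) ** 2 * sub["heat_se_w"].to_numpy() ** 2
            ses[name] = float(np.sqrt(np.sum(f ** 2 * var_r)))
        se_icl = (np.hypot(ses["i_t"], ses["i_a"]) / self.f_cl
                  if self.printed_form
                  else np.hypot(ses["i_t"], ses["i_a"] / self.f_cl))

        clothed_avg = avg[avg.condition == "clothed"]
        local = pd.DataFrame({
            "segment": clothed_avg["segment"].to_numpy(),
            "area_m2": clothed_avg["area_m2"].to_numpy(),
            "r_local_m2k_w": ((clothed_avg["tsurf_c"] - self.ta_c)
                              * clothed_avg["area_m2"]
                              / clothed_avg["heat_w"]).to_numpy(),
        })
        nude_avg = avg[avg.condition == "nude"].set_index("segment")
        local["r_air_m2k_w"] = ((nude_avg["tsurf_c"] - self.ta_c)
                                * nude_avg["area_m2"]
                                / nude_avg["heat_w"]).reindex(local["segment"]).to_numpy()
        local["f_i"] = local["area_m2"] / local["area_m2"].sum()

        return InsulationResults(
            model=self, i_t_m2kw=i_t, i_a_m2kw=i_a, i_cl_m2kw=i_cl,
            i_t_se=ses["i_t"], i_a_se=ses["i_a"], i_cl_se=float(se_icl),
            local=local, dropped_segments=tuple(dropped))


@dataclass
class InsulationResults:
    """Fitted whole-body and local insulations with standard errors."""

    model: SerialInsulationModel
    i_t_m2kw: float
    i_a_m2kw: float
    i_cl_m2kw: float
    i_t_se: float
    i_a_se: float
    i_cl_se: float
    local: pd.DataFrame
    dropped_segments: tuple = ()

    @property
    def i_t_clo(self) -> float:
        return self.i_t_m2kw / CLO

    @property
    def i_a_clo(self) -> float:
        return self.i_a_m2kw / CLO

    @property
    def i_cl_clo(self) -> float:
        return self.i_cl_m2kw / CLO

    @property
    def f_cl(self) -> float:
        return self.model.f_cl

    def to_dict(self) -> dict:
        return {
            "i_t_m2kw": self.i_t_m2kw, "i_a_m2kw": self.i_a_m2kw,
            "i_cl_m2kw": self.i_cl_m2kw,
            "i_t_clo": self.i_t_clo, "i_a_clo": self.i_a_clo,
            "i_cl_clo": self.i_cl_clo, "f_cl": self.f_cl,
            "dropped_segments": list(self.dropped_segments),
            "local": self.local.to_dict(orient="records"),
        }

    def summary(self) -> str:
        head = [
            "Serial-model clothing insulation",
            "=" * 48,
            f"{'':24s}{'m2K/W':>10s}{'clo':>10s}",
            f"{'total I_t':24s}{self.i_t_m2kw:10.4f}{self.i_t_clo:10.3f}",
            f"{'air layer I_a':24s}{self.i_a_m2kw:10.4f}{self.i_a_clo:10.3f}",
            f"{'basic I_cl':24s}{self.i_cl_m2kw:10.4f}{self.i_cl_clo:10.3f}",
            f"{'clothing area factor':24s}{self.f_cl:10.2f}",
            "-" * 48,
            f"{'segment':16s}{'f_i':>8s}{'R_total':>12s}{'R_air':>12s}",
        ]
        for row in self.local.itertuples():
            head.append(f"{row.segment:16s}{row.f_i:8.3f}"
                        f"{row.r_local_m2k_w:12.4f}{row.r_air_m2k_w:12.4f}")
        if self.dropped_segments:
            head.append(f"dropped (single condition): "
                        f"{', '.join(self.dropped_segments)}")
        return "\n".join(head)
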