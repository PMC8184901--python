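"""AI-vs-expert comparison arithmetic: relative differences and tables.

The comparison convention, reconstructed cell-by-cell from the published
8-patient ¹⁷⁷Lu-DOTATOC cohort this package ships as reference data:

* per-side signed difference  Di = round(100·(AI − Ex)/Ex)  to the
  nearest integer (half away from zero); negative = AI underestimates;
* per-patient mean = mean of the **absolute** per-side integers (an
  exact multiple of 0.5 by construction); a missing side contributes
  nothing and a single-sided patient keeps that side's |Di|;
* cohort average = mean of patient means, one decimal.

Rounding order matters: per-side integers first, then means — the only
order that reproduces the published half-integer cells.  The spill-out
re-analysis uses a different printed precision (two decimals, truncated
toward zero) and has its own helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

SIDES = ("left", "right")
QUANTITIES = ("mass_g", "mean_dose_Gy")
PROVENANCES = ("expert", "ai")


@dataclass
class MethodValue:
    """One table cell: a mass or mean dose from one provenance."""

    patient: str
    side: str
    quantity: str
    provenance: str
    value: float | None  # None = organ absent in the patient ("*")

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if self.value is not None and self.value <= 0:
            raise ValueError("values must be positive unless missing")

    @property
    def missing(self) -> bool:
        return self.value is None


def _round_half_away(x: float, decimals: int = 0) -> float:
    scale = 10**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def relative_difference(ai: float | None, ex: float | None) -> float | None:
    """Signed percent difference round(100·(ai−ex)/ex), integer, half away.

    Negative means the automated value underestimates the expert value.
    Missing inputs propagate as ``None``.
    """
    if ai is None or ex is None:
        return None
    if ex <= 0:
        raise ValueError("expert (reference) value must be positive")
    return _round_half_away(100.0 * (ai - ex) / ex)


def patient_mean(di_left: float | None, di_right: float | None) -> float:
    """Mean of the absolute per-side differences; one side may be missing."""
    present = [abs(d) for d in (di_left, di_right) if d is not None]
    if not present:
        raise ValueError("patient has no organ on either side")
    return sum(present) / len(present)


def cohort_average(patient_means: list[float]) -> float:
    """Cohort mean of the per-patient means, one decimal, half away from zero."""
    if not patient_means:
        raise ValueError("cohort is empty")
    return _round_half_away(float(np.mean(patient_means)), decimals=1)


def _truncate(x: float, decimals: int) -> float:
    scale = 10**decimals
    return math.trunc(x * scale) / scale


def spillout_analysis(
    doses_ai: dict[str, float], doses_ex: dict[str, float]
) -> dict[str, float]:
    """Per-side underestimation magnitude 100·(ex−ai)/ex, plus the average.

    Per-side values are printed at two decimals truncated toward zero
    (matching the published worked example, where 2.7397 prints as 2.73);
    the average is reported at one decimal.
    """
    out: dict[str, float] = {}
    for side in SIDES:
        ai, ex = doses_ai[side], doses_ex[side]
        if ex <= 0 or ai <= 0:
            raise ValueError("doses must be positive")
        out[side] = _truncate(abs(100.0 * (ex - ai) / ex), 2)
    out["average"] = _round_half_away(float(np.mean([out[s] for s in SIDES])), 1)
    return out


@dataclass
class DiffReport:
    """Per-side, per-patient and cohort difference summary for one quantity."""

    quantity: str
    per_side_di: dict[tuple[str, str], float | None]  # (patient, side) -> Di %
    per_patient_mean: dict[str, float]
    cohort_avg: float
    rounding_trace: list[str] = field(default_factory=list)


def build_diff_report(records: list[MethodValue], quantity: str) -> DiffReport:
    """Regenerate the Di / Mean-Di / cohort-average rows for one quantity."""
    table: dict[tuple[str, str, str], MethodValue] = {}
    for r in records:
        if r.quantity != quantity:
            continue
        key = (r.patient, r.side, r.provenance)
        if key in table:
            raise ValueError(f"duplicate record {key}")
        table[key] = r
    patients = sorted({p for p, _, _ in table}, key=str)
    per_side: dict[tuple[str, str], float | None] = {}
    per_patient: dict[str, float] = {}
    trace: list[str] = []
    for p in patients:
        dis = {}
        for side in SIDES:
            ai = table.get((p, side, "ai"))
            ex = table.get((p, side, "expert"))
            if ai is None or ex is None or ai.missing or ex.missing:
                per_side[(p, side)] = None
                dis[side] = None
                continue
            raw = 100.0 * (ai.value - ex.value) / ex.value
            di = relative_difference(ai.value, ex.value)
            per_side[(p, side)] = di
            dis[side] = di
            if abs(raw - di) > 0.45:
                trace.append(
                    f"patient {p} {side} {quantity}: raw {raw:+.2f}% rounds to "
                    f"{di:+.0f}% (large rounding step)"
                )
        per_patient[p] = patient_mean(dis["left"], dis["right"])
    avg = cohort_average(list(per_patient.values()))
    raw_avg = float(np.mean(list(per_patient.values())))
    if abs(raw_avg - avg) > 1e-9:
        trace.append(f"cohort {quantity}: mean of patient means {raw_avg:.4f} -> {avg}")
    return DiffReport(
        quantity=quantity,
        per_side_di=per_side,
        per_patient_mean=per_patient,
        cohort_avg=avg,
        rounding_trace=trace,
    )


# ---------------------------------------------------------------------------
# Record I/O and table rendering
# ---------------------------------------------------------------------------


def load_records(path_or_df: str | Path | pd.DataFrame) -> list[MethodValue]:
    """Load MethodValue records from CSV columns patient,side,quantity,provenance,value."""
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, dtype={"patient": str})
    )
    records = []
    for row in df.itertuples(index=False):
        value = None if pd.isna(row.value) else float(row.value)
        records.append(
            MethodValue(
                patient=str(row.patient),
                side=row.side,
                quantity=row.quantity,
                provenance=row.provenance,
                value=value,
            )
        )
    return records


def load_published_dataset4() -> list[MethodValue]:
    """The published 8-patient kidney mass/dose tables shipped with the package."""
    with resources.files("voxdose.data").joinpath("dataset4_tables.csv").open() as fh:
        return load_records(pd.read_csv(fh, dtype={"patient": str}))


def render_tables(records: list[MethodValue], quantity: str) -> pd.DataFrame:
    """Render the published table layout: Ex/AI/Di rows × patient columns.

    Missing organs print as ``*``; negative differences keep the
    ``(-) n`` text convention of the source tables.  The ``Avg.`` column
    holds the cohort average of the Mean-Di row.
    """
    patients = sorted({r.patient for r in records if r.quantity == quantity}, key=str)
    unit0 = "g" if quantity == "mass_g" else "Gy"
    row_names = [
        f"{tag} {ptag}({unit0})"
        for tag in ("L Kid", "R Kid")
        for ptag in ("Ex", "AI")
    ]
    if not patients:
        return pd.DataFrame(
            index=[*row_names[:2], "L Kid Di(%)", *row_names[2:], "R Kid Di(%)",
                   "Mean Di(%)"],
            columns=["Avg."],
        )
    rep = build_diff_report(records, quantity)
    by_key = {
        (r.patient, r.side, r.provenance): r
        for r in records
        if r.quantity == quantity
    }
    if len(by_key) < sum(1 for r in records if r.quantity == quantity):
        raise ValueError("duplicate (patient, side, provenance) records")
    unit = "g" if quantity == "mass_g" else "Gy"

    def fmt_value(r: MethodValue | None) -> str:
        if r is None or r.missing:
            return "*"
        return f"{r.value:g}"

    def fmt_di(di: float | None) -> str:
        if di is None:
            return "*"
        return f"(-) {abs(di):g}" if di < 0 else f"{di:g}"

    rows = {}
    for side, tag in (("left", "L Kid"), ("right", "R Kid")):
        for prov, ptag in (("expert", "Ex"), ("ai", "AI")):
            rows[f"{tag} {ptag}({unit})"] = [
                fmt_value(by_key.get((p, side, prov))) for p in patients
            ] + [""]
        rows[f"{tag} Di(%)"] = [fmt_di(rep.per_side_di[(p, side)]) for p in patients] + [""]
    rows["Mean Di(%)"] = [f"{rep.per_patient_mean[p]:g}" for p in patients] + [
        f"{rep.cohort_avg:g}"
    ]
    return pd.DataFrame(rows, index=[*patients, "Avg."]).T
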