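"""CSV/JSON plumbing for streams, bout tables, daily PROs and cohorts."""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clinimetrics import CohortTable
from .signal import AccelStream, ActivityBout, InputError
from .summarize import DailyPRO, DailySummary, WeeklySummary

ACCEL_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g"]


def read_accel_csv(path: str | Path, sidecar: str | Path | None = None) -> AccelStream:
    """Read a raw stream CSV (columns t_s, ax_g, ay_g, az_g, header required).

    An optional sidecar JSON provides ``start_time`` and ``rate_hz``;
    otherwise the rate is inferred from the median timestamp spacing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise InputError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: missing required column(s) {missing}; "
            f"header must contain {ACCEL_COLUMNS}"
        )
    for col in ACCEL_COLUMNS:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise InputError(
                f"{path}: malformed value in column {col!r} at data row "
                f"{int(bad[0]) + 2} (1-based, counting the header)"
            )
    rate = None
    start_time = None
    if sidecar is None:
        candidate = path.with_suffix(".json")
        sidecar = candidate if candidate.exists() else None
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        rate = meta.get("rate_hz")
        start_time = meta.get("start_time")
    if rate is None:
        diffs = np.diff(df["t_s"].to_numpy(dtype=float))
        if len(diffs) == 0 or np.median(diffs) <= 0:
            raise InputError(f"{path}: cannot infer sampling rate from t_s")
        rate = 1.0 / float(np.median(diffs))
    return AccelStream(
        ax=df["ax_g"].to_numpy(dtype=float),
        ay=df["ay_g"].to_numpy(dtype=float),
        az=df["az_g"].to_numpy(dtype=float),
        rate=float(rate),
        start_time=start_time,
    )


def write_accel_csv(
    stream: AccelStream, path: str | Path, sidecar: bool = True
) -> None:
    path = Path(path)
    t = np.arange(len(stream)) / stream.rate
    pd.DataFrame(
        {"t_s": t, "ax_g": stream.ax, "ay_g": stream.ay, "az_g": stream.az}
    ).to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        meta = {"rate_hz": stream.rate, "start_time": stream.start_time}
        path.with_suffix(".json").write_text(json.dumps(meta))


def write_bout_table(
    bouts_by_day: dict[object, Sequence[ActivityBout]],
    path: str | Path,
    rate: float,
    header_comment: str | None = None,
) -> None:
    """Bout table CSV: day, bout_start_s, bout_end_s, duration_s, ac, intensity."""
    rows = []
    for day, bouts in bouts_by_day.items():
        for b in bouts:
            rows.append(
                {
                    "day": day,
                    "bout_start_s": b.start_index / rate,
                    "bout_end_s": b.end_index / rate,
                    "duration_s": b.duration_s,
                    "ac": b.activity_count,
                    "intensity": b.intensity,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["day", "bout_start_s", "bout_end_s", "duration_s", "ac",
                 "intensity"],
    )
    _write_with_comment(df, path, header_comment)


def write_daily_table(
    days: Sequence[DailySummary], path: str | Path,
    header_comment: str | None = None,
) -> None:
    df = pd.DataFrame(
        [
            {
                "date": d.date.isoformat(),
                "wear_time_s": d.wear_time_s,
                "active_time_ratio": d.active_time_ratio,
                "mean_ac_per_active_minute": d.mean_ac_per_active_minute,
                "prop_lia": d.prop_lia,
                "prop_mia": d.prop_mia,
                "prop_hia": d.prop_hia,
                "n_bouts": d.n_bouts,
                "valid": d.valid,
            }
            for d in days
        ]
    )
    _write_with_comment(df, path, header_comment)


def write_weekly_table(
    weeks: Sequence[WeeklySummary], path: str | Path,
    subject: object = None, header_comment: str | None = None,
) -> None:
    rows = []
    for w in weeks:
        row = {"week_label": w.week_label, "n_valid_days": w.n_valid_days,
               "valid": w.valid}
        if subject is not None:
            row = {"subject_id": subject, **row}
        row.update(w.means)
        rows.append(row)
    _write_with_comment(pd.DataFrame(rows), path, header_comment)


def read_daily_pro_csv(path: str | Path) -> list[DailyPRO]:
    """Daily PRO CSV: date, vas_pain_mm, vas_activity_mm, sane (blank = missing)."""
    df = pd.read_csv(path)
    required = {"date", "vas_pain_mm", "vas_activity_mm", "sane"}
    if not required.issubset(df.columns):
        raise InputError(
            f"{path}: daily PRO CSV needs columns {sorted(required)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            DailyPRO(
                date=dt.date.fromisoformat(str(row["date"])),
                vas_pain_mm=_opt(row["vas_pain_mm"]),
                vas_activity_mm=_opt(row["vas_activity_mm"]),
                sane=_opt(row["sane"]),
            )
        )
    return out


def _opt(v) -> float | None:
    v = pd.to_numeric(v, errors="coerce")
    return None if pd.isna(v) else float(v)


def read_cohort_csv(
    scores_path: str | Path, grcs_path: str | Path
) -> CohortTable:
    """Cohort from a long tidy scores CSV plus a GRCS anchor CSV."""
    long = pd.read_csv(scores_path, comment="#")
    grcs = pd.read_csv(grcs_path, comment="#")
    return CohortTable.from_long(long, grcs)


def write_cohort_csv(
    cohort: CohortTable, scores_path: str | Path, grcs_path: str | Path,
    header_comment: str | None = None,
) -> None:
    long = (
        cohort.scores.stack(future_stack=True)
        .rename("value")
        .reset_index()
        .rename(columns={"level_2": "variable"})
    )
    long.columns = ["subject_id", "timepoint", "variable", "value"]
    _write_with_comment(long, scores_path, header_comment)
    _write_with_comment(
        cohort.grcs.reset_index(), grcs_path, header_comment
    )


def _write_with_comment(
    df: pd.DataFrame, path: str | Path, comment: str | None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)
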