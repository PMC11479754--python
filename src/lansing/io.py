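"""Reading and writing cohort files and result tables.

The canonical cohort file is a long-format UTF-8 CSV with the exact header
``individual_id,group,day,offspring_count``: one row per individual per
observed day, days consecutive from 1 to that individual's lifespan, and a
final-day count >= 1 (the operational death definition). Validation failures
name the offending individual and day.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import ReproductionSchedule

__all__ = ["read_cohort", "write_cohort", "lifespans_by_group", "write_manifest"]

COHORT_COLUMNS = ["individual_id", "group", "day", "offspring_count"]


class CohortValidationError(ValueError):
    """A cohort file violated the long-format contract."""


def write_cohort(schedules, path) -> None:
    """Serialize schedules to the canonical long-format CSV."""
    rows = []
    for s in schedules:
        for day, count in enumerate(s.counts, start=1):
            rows.append((s.individual_id, s.group, day, count))
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort(path) -> list[ReproductionSchedule]:
    """Parse and validate a long-format cohort CSV into schedules.

    Raises :class:`CohortValidationError` naming the individual (and missing
    or offending day) for gaps, non-integer entries, or a zero final-day
    count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if list(df.columns) != COHORT_COLUMNS:
        raise CohortValidationError(
            f"{path}: expected header {','.join(COHORT_COLUMNS)}, got {','.join(df.columns)}"
        )
    for col in ("day", "offspring_count"):
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     | (pd.to_numeric(df[col], errors="coerce") % 1 != 0)]
            rows = (bad.index + 2).tolist()[:5]  # +2: header + 1-based
            raise CohortValidationError(f"{path}: non-integer {col} at file rows {rows}")
    schedules = []
    for ind, sub in df.groupby("individual_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise CohortValidationError(f"{path}: individual {ind!r} has multiple group labels {list(groups)}")
        days = sub["day"].to_numpy()
        expected = np.arange(1, days.size + 1)
        order = np.argsort(days)
        if not np.array_equal(days[order], expected):
            missing = sorted(set(range(1, int(days.max()) + 1)) - set(days.tolist()))
            raise CohortValidationError(
                f"{path}: individual {ind!r} has non-consecutive days"
                + (f"; missing day(s) {missing[:5]}" if missing else "; duplicated days")
            )
        counts = sub["offspring_count"].to_numpy()[order]
        if counts[-1] < 1:
            raise CohortValidationError(
                f"{path}: individual {ind!r} has offspring_count 0 on its final day "
                f"{days.size}; death is defined as the day the last offspring detaches"
            )
        if np.any(counts < 0):
            raise CohortValidationError(f"{path}: individual {ind!r} has negative counts")
        sched = ReproductionSchedule(str(ind), str(groups[0]), tuple(int(c) for c in counts))
        sched.validate()
        schedules.append(sched)
    if not schedules:
        raise CohortValidationError(f"{path}: no individuals")
    return schedules


def lifespans_by_group(schedules) -> dict[str, np.ndarray]:
    """Integer lifespan vectors keyed by group label, in file order."""
    out: dict[str, list[int]] = {}
    for s in schedules:
        out.setdefault(s.group, []).append(s.lifespan)
    return {g: np.array(v, dtype=np.int64) for g, v in out.items()}


def write_manifest(path, *, seed, command: str, parameters: dict) -> None:
    """Write the JSON run manifest that makes an output reproducible."""
    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "parameters": parameters,
        "package_version": __version__,
        "python_version": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
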