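"""CSV data model and the grouped normalization workflow.

Input files follow a fixed layout: the first two columns are ``Luc`` and
``Ren`` (firefly and Renilla luminescence in RLU), the third is
``Construct`` (the firefly reporter assayed), and every further column is
an experimental condition whose values are categorical level labels, e.g.::

    Luc,Ren,Construct,OHT,Cytokine
    35.2,4.1,Cebpa0,no,IL3
    ...

Normalization partitions the rows by the observed combinations of all
non-ignored columns and estimates one slope (with an optional bootstrap
confidence interval) per group.  Groups too small for the requested
estimator are reported with a failure marker rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import ESTIMATORS, EstimationError, ReplicateSet
from .simulator import SimulatedExperiment
from .uncertainty import BootstrapError, BootstrapSpec, bootstrap_ci

__all__ = [
    "LuminescenceTable",
    "read_luminescence_csv",
    "calc_slopes_cis",
    "write_results_csv",
    "normalize_to_reference",
    "experiment_to_table",
    "CI_METHODS",
]

_REQUIRED = ("Luc", "Ren", "Construct")

#: Interval identifiers accepted by :func:`calc_slopes_cis`.
CI_METHODS = ("boot", "boot-positive", "none")

_CI_TO_BOOTSTRAP = {"boot": "basic", "boot-positive": "basic_positive"}

#: Columns appended to the group keys in a result table.
RESULT_COLUMNS = ("slope", "ci_lower", "ci_upper", "n_replicates", "method", "converged", "status")


@dataclass(frozen=True)
class LuminescenceTable:
    """A validated luminescence table plus its condition-column names."""

    frame: pd.DataFrame
    condition_columns: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def _validate_frame(frame: pd.DataFrame) -> LuminescenceTable:
    cols = list(frame.columns)
    if cols[:1] != ["Luc"] or cols[1:2] != ["Ren"] or cols[2:3] != ["Construct"]:
        raise ValueError(
            "the first three columns must be named exactly 'Luc', 'Ren', 'Construct' "
            f"(got {cols[:3]})"
        )
    frame = frame.copy()
    for col in ("Luc", "Ren"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.index[numeric.isna() | ~np.isfinite(numeric.astype(float))]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based counting
            raise ValueError(
                f"column {col!r} has a non-numeric or non-finite value at file row "
                f"{int(bad[0]) + 2}"
            )
        frame[col] = numeric.astype(float)
    condition_columns = tuple(cols[3:])
    # construct and condition labels are categorical even when they look numeric
    for col in ("Construct", *condition_columns):
        frame[col] = frame[col].astype(str)
    return LuminescenceTable(frame=frame, condition_columns=condition_columns)


def read_luminescence_csv(path) -> LuminescenceTable:
    """Read and validate a luminescence CSV (``Luc,Ren,Construct,<conditions...>``)."""
    frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    return _validate_frame(frame)


def calc_slopes_cis(
    table: LuminescenceTable,
    alpha: float = 0.05,
    method: str = "reiv",
    ci_method: str = "boot-positive",
    ignore: tuple[str, ...] = ("Luc", "Ren"),
    seed: int | None = None,
    n_boot: int = 999,
) -> pd.DataFrame:
    """Estimate normalized activity per construct x condition group.

    Rows are partitioned by the distinct observed combinations of every
    column not in ``ignore`` (which must contain at least ``Luc`` and
    ``Ren``).  For each group the estimator is run on (Ren -> R, Luc -> F)
    and, unless ``ci_method`` is "none", a basic bootstrap interval at level
    ``alpha`` is attached ("boot-positive" clamps the lower bound at 0).

    Returns a result table with one row per group, in the order groups first
    appear in the file: the group-key columns followed by ``slope``,
    ``ci_lower``, ``ci_upper``, ``n_replicates``, ``method``, ``converged``
    and ``status`` ("ok", or the failure message for groups the estimator
    could not fit).
    """
    if not {"Luc", "Ren"} <= set(ignore):
        raise ValueError("ignore must contain at least 'Luc' and 'Ren'")
    if method not in ESTIMATORS:
        raise ValueError(
            f"unknown method {method!r}; options: {', '.join(ESTIMATORS)}"
        )
    if ci_method not in CI_METHODS:
        raise ValueError(
            f"unknown CI method {ci_method!r}; options: {', '.join(CI_METHODS)}"
        )
    frame = table.frame
    group_cols = [c for c in frame.columns if c not in set(ignore)]
    if not group_cols:
        raise ValueError("no grouping columns remain after applying the ignore set")

    rows = []
    if len(frame):
        grouped = frame.groupby(group_cols, sort=False, observed=True)
        # one independent, reproducible bootstrap stream per group
        children = np.random.SeedSequence(seed).spawn(grouped.ngroups)
        for (key, sub), child in zip(grouped, children):
            key = key if isinstance(key, tuple) else (key,)
            row = dict(zip(group_cols, key))
            row.update(
                slope=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                n_replicates=len(sub), method=method, converged=False, status="ok",
            )
            try:
                data = ReplicateSet(
                    renilla=sub["Ren"].to_numpy(), firefly=sub["Luc"].to_numpy()
                )
                est = ESTIMATORS[method](data)
                row["slope"] = est.activity
                row["converged"] = est.converged
                if ci_method != "none":
                    lo, hi = bootstrap_ci(
                        data,
                        method,
                        BootstrapSpec(
                            n_boot=n_boot,
                            alpha=alpha,
                            method=_CI_TO_BOOTSTRAP[ci_method],
                            seed=int(child.generate_state(1)[0] % (2**31)),
                        ),
                    )
                    row["ci_lower"], row["ci_upper"] = lo, hi
            except (EstimationError, BootstrapError, ValueError) as exc:
                row["status"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows, columns=[*group_cols, *RESULT_COLUMNS])


def normalize_to_reference(
    results: pd.DataFrame, reference_construct: str, construct_col: str = "Construct"
) -> pd.DataFrame:
    """Express slopes relative to a reference construct, per condition combination.

    Adds a ``relative_activity`` column: each group's slope divided by the
    slope of ``reference_construct`` within the same condition levels.
    Confidence intervals are not propagated.  Condition combinations lacking
    the reference yield NaN.
    """
    if construct_col not in results.columns:
        raise ValueError(f"result table has no {construct_col!r} column")
    out = results.copy()
    cond_cols = [
        c for c in results.columns if c not in RESULT_COLUMNS and c != construct_col
    ]
    ref = results[results[construct_col] == reference_construct]
    if ref.empty:
        raise ValueError(f"reference construct {reference_construct!r} not found")
    if cond_cols:
        ref_map = ref.set_index(cond_cols)["slope"]
        keys = pd.MultiIndex.from_frame(out[cond_cols]) if len(cond_cols) > 1 else out[cond_cols[0]]
        ref_slopes = ref_map.reindex(keys).to_numpy()
    else:
        ref_slopes = np.full(len(out), float(ref["slope"].iloc[0]))
    out["relative_activity"] = out["slope"].to_numpy() / ref_slopes
    return out


def write_results_csv(results: pd.DataFrame, path) -> None:
    """Write a result table to CSV at full decimal precision (round-trip exact)."""
    results.to_csv(path, index=False, float_format="%.17g")


def experiment_to_table(
    experiment: SimulatedExperiment, construct: str = "sim", **conditions: str
) -> LuminescenceTable:
    """Render a simulated experiment in the standard table layout.

    Extra keyword arguments become condition columns, so simulated data flow
    through the same I/O path as real measurements.
    """
    frame = pd.DataFrame(
        {
            "Luc": experiment.data.firefly,
            "Ren": experiment.data.renilla,
            "Construct": construct,
            **{k: str(v) for k, v in conditions.items()},
        }
    )
    return _validate_frame(frame)
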