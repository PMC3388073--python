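"""Unreplicated time-course DEG calling and 8-way expression-pattern grouping.

For single-sample time courses (one array per timepoint, as in a
cholesterol-depletion series on a prostate cell line) there is no
within-timepoint variance, so
genes are called by fold change alone: a gene is up at timepoint t when
value(t) - value(baseline) exceeds the log2 threshold, down when it falls
below the negated threshold, otherwise unchanged (strict inequalities).

With two post-baseline timepoints each called gene carries an ordered state
pair (state at 3 h, state at 16 h) over {up, none, down}; excluding the
all-none pair leaves 3^2 - 1 = 8 pattern classes.  Patterns are numbered
lexicographically with up < none < down, so (up, up) = 1 captures the
sustained early responders and (down, down) = 8 their mirror image, while
(none, up) = 4 and (none, down) = 5 are the late-only responders.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .io import CholnetError, ExpressionMatrix, RunConfig

_STATE_ORDER = ("up", "none", "down")

#: Ordered (state_t1, state_t2) pair -> pattern id 1..8; (none, none) excluded.
PATTERNS: dict[tuple[str, str], int] = {
    pair: i + 1
    for i, pair in enumerate(
        p for p in product(_STATE_ORDER, repeat=2) if p != ("none", "none")
    )
}


def call_timecourse(
    matrix: ExpressionMatrix,
    baseline: str,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-gene fold changes and up/down/none states versus the baseline.

    Design labels are timepoints with exactly one sample each; returns a
    DataFrame indexed by gene with columns ``log2fc_<tp>`` and
    ``state_<tp>`` for every non-baseline timepoint (file order preserved).
    """
    config = config or RunConfig()
    groups = matrix.groups()
    if baseline not in groups:
        raise CholnetError(f"baseline timepoint {baseline!r} not in design labels {sorted(groups)}")
    replicated = [tp for tp, samples in groups.items() if len(samples) > 1]
    if replicated:
        raise CholnetError(
            f"timepoints {replicated} have replicates; use the integrative "
            "two-group test for replicated designs")

    tau = config.fc_threshold
    base = matrix.values[groups[baseline][0]]
    out = pd.DataFrame(index=matrix.values.index.rename("gene"))
    for tp, samples in groups.items():
        if tp == baseline:
            continue
        fc = matrix.values[samples[0]] - base
        state = np.where(fc > tau, "up", np.where(fc < -tau, "down", "none"))
        out[f"log2fc_{tp}"] = fc
        out[f"state_{tp}"] = state
    return out


def assign_patterns(calls: pd.DataFrame, timepoints: list[str]) -> pd.DataFrame:
    """Map each called gene to one of the 8 two-timepoint state patterns.

    ``timepoints`` are the two non-baseline timepoints in temporal order.
    Genes with no non-none state get pattern id 0 (uncalled).
    """
    if len(timepoints) != 2:
        raise CholnetError(f"exactly 2 non-baseline timepoints required, got {timepoints}")
    for tp in timepoints:
        if f"state_{tp}" not in calls.columns:
            raise CholnetError(f"timepoint {tp!r} missing from calls")
    out = calls.copy()
    s1, s2 = (calls[f"state_{tp}"] for tp in timepoints)
    out["pattern_id"] = [
        PATTERNS.get((a, b), 0) for a, b in zip(s1, s2)
    ]
    return out
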