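"""Validation statistics: threshold calibration and 2x2 association tests.

Covers the clinical-validation toolkit around the HRD score: deriving HRD
positivity (high score OR a BRCA1/2 mutation), BRCA status assignment from
annotated variants, agreement rates against reference labels, the
5th-percentile threshold calibration on BRCA-mutated cohorts, the
window-size mode-frequency sweep, and odds ratios with Woolf confidence
intervals plus Fisher/chi-squared p-values for 2x2 tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "association",
    "agreement_rate",
    "calibrate_threshold",
    "mode_frequency",
    "derive_hrd_positivity",
    "assign_brca_status",
]

PATHOGENIC_LABELS = frozenset({"pathogenic", "likely pathogenic", "likely_pathogenic"})
BRCA_GENES = frozenset({"BRCA1", "BRCA2"})


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 integer counts laid out as [[a, b], [c, d]].

    Rows are the exposure (e.g. HRD-positive first), columns the outcome
    (e.g. responder first); the odds ratio is a*d / (b*c).
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("event", "no event")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test: str
    continuity_corrected: bool = False


def association(
    table: ContingencyTable,
    test: str = "auto",
    ci_level: float = 0.95,
) -> AssociationResult:
    """Odds ratio with a Woolf CI and an exact or chi-squared p-value.

    The Woolf interval is exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    ``test`` is "fisher", "chi2", or "auto" (Fisher whenever any expected
    cell count is below 5, the usual small-sample rule).  A zero cell
    triggers the Haldane-Anscombe 0.5 continuity correction for the OR/CI,
    flagged in the result.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    z = sps.norm.ppf(0.5 + ci_level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(oratio) - z * se)
    ci_high = math.exp(math.log(oratio) + z * se)

    counts = table.counts
    if test == "auto":
        total = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
        test = "fisher" if (expected < 5).any() else "chi2"
    if test == "fisher":
        _, p = sps.fisher_exact(counts, alternative="two-sided")
    elif test == "chi2":
        _, p, _, _ = sps.chi2_contingency(counts, correction=True)
    else:
        raise ValueError("test must be 'fisher', 'chi2', or 'auto'")
    return AssociationResult(
        odds_ratio=oratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        test=test,
        continuity_corrected=corrected,
    )


def agreement_rate(
    classified_high: Sequence[bool],
    reference_positive: Sequence[bool],
    mode: str = "overall",
) -> float:
    """Agreement between HRD-high calls and a binary reference status.

    ``overall``: fraction of samples whose call matches the reference.
    ``positive``: fraction of reference-positive samples called high (the
    BRCA-positive agreement rate).  ``negative``: fraction of
    reference-negative samples called low.  Returns NaN when the relevant
    denominator is empty.
    """
    calls = np.asarray(classified_high, dtype=bool)
    ref = np.asarray(reference_positive, dtype=bool)
    if len(calls) != len(ref):
        raise ValueError("calls and reference labels differ in length")
    if mode == "overall":
        return float((calls == ref).mean()) if len(ref) else float("nan")
    if mode == "positive":
        return float(calls[ref].mean()) if ref.any() else float("nan")
    if mode == "negative":
        return float((~calls[~ref]).mean()) if (~ref).any() else float("nan")
    raise ValueError("mode must be 'overall', 'positive', or 'negative'")


def calibrate_threshold(
    scores: Sequence[int], target_agreement: float = 0.95
) -> tuple[int, float]:
    """Largest integer threshold keeping the positive agreement at target.

    Given HRD scores of reference-positive (BRCA-mutated) samples, returns
    the largest integer t such that the fraction of scores >= t is at least
    ``target_agreement`` — the discrete form of setting the cut-off at the
    (1 - target) percentile of the calibration scores — together with the
    agreement actually achieved at t.
    """
    s = np.sort(np.asarray(scores, dtype=np.int64))
    n = len(s)
    if n == 0:
        raise ValueError("no calibration scores")
    if (s < 0).any():
        raise ValueError("scores must be non-negative")
    if n < 20:
        import warnings

        warnings.warn("fewer than 20 calibration scores; threshold may be unstable")
    m = math.ceil(target_agreement * n)  # required count of scores >= t
    t = int(s[n - m])
    achieved = float((s >= t).mean())
    return t, achieved


def mode_frequency(lcna_matrix: pd.DataFrame) -> pd.Series:
    """Per-window-size count of samples whose LCNA count equals their mode.

    ``lcna_matrix`` has one row per sample and one column per window size.
    For each sample, cells equal to the sample's modal count score 1 (all
    tied top values count as the mode), others 0; the column sums say how
    many samples each window size "covers".
    """
    if lcna_matrix.isna().any().any():
        raise ValueError("LCNA matrix must be complete")
    indicators = pd.DataFrame(
        0, index=lcna_matrix.index, columns=lcna_matrix.columns, dtype=int
    )
    for sample, row in lcna_matrix.iterrows():
        counts = row.value_counts()
        top = counts.max()
        modes = set(counts[counts == top].index)
        indicators.loc[sample] = row.isin(modes).astype(int)
    return indicators.sum(axis=0)


def derive_hrd_positivity(
    hrd_score: int | None,
    brca_status: str,
    threshold: int = 10,
) -> str:
    """HRD-positive iff the score is high OR BRCA1/2 is mutated.

    Returns "positive", "negative", or "unknown" (when either input is
    unavailable); unknowns are excluded from downstream tables.
    """
    if brca_status == "mutated":
        return "positive"
    if hrd_score is None or brca_status not in ("mutated", "non-mutated"):
        return "unknown"
    return "positive" if hrd_score >= threshold else "negative"


def assign_brca_status(
    variants: pd.DataFrame,
    min_supporting_reads: int = 3,
) -> str:
    """BRCA status from annotated variant records of one sample.

    A sample is "mutated" when at least one BRCA1/BRCA2 record is annotated
    pathogenic or likely pathogenic by either clinical annotator and has
    strictly more than ``min_supporting_reads`` supporting allele reads;
    records originating from an external somatic catalog (``origin ==
    "somatic_catalog"``) qualify regardless of read support.

    Expected columns: ``gene``, ``intervar``, ``clinvar``,
    ``supporting_reads``; optional ``origin``.
    """
    if variants.empty:
        return "non-mutated"
    df = variants[variants["gene"].isin(BRCA_GENES)]
    if df.empty:
        return "non-mutated"
    if "origin" in df.columns and (df["origin"] == "somatic_catalog").any():
        return "mutated"

    def norm(col: pd.Series) -> pd.Series:
        return col.fillna("").str.strip().str.lower().str.replace("_", " ")

    pathogenic = norm(df["intervar"]).isin(PATHOGENIC_LABELS) | norm(df["clinvar"]).isin(
        PATHOGENIC_LABELS
    )
    supported = df["supporting_reads"] > min_supporting_reads
    return "mutated" if (pathogenic & supported).any() else "non-mutated"
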