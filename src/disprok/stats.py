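"""Significance-testing protocol for between-category disorder comparisons.

The comparison pipeline reduces each category to its 25% most disordered
proteins (disorder distributions are heavily zero-inflated for long length
classes, so comparing full distributions mostly compares the zero mass),
screens normality with a one-sample Kolmogorov-Smirnov test against a normal
with the sample's mean and SD, and compares means with Welch's
unequal-variance two-sided t-test.

The KS p-value uses estimated parameters and is therefore approximate
(anti-conservative); it serves as a screen, not an inferential endpoint.
No multiple-testing correction is applied by default; Benjamini-Hochberg is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io import Dataset
from .grouping import proteins_in_group
from .regions import disordered_run_lengths

__all__ = [
    "TestResult",
    "top_fraction",
    "t_test",
    "ks_normality",
    "compare_categories",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def top_fraction(values: Sequence[float] | np.ndarray, fraction: float = 0.25) -> np.ndarray:
    """The ``ceil(n * fraction)`` largest values.

    Ties at the cut are included up to the count, broken deterministically by
    original index (earlier indices win).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    k = int(np.ceil(arr.size * fraction))
    # stable sort on -value keeps earlier indices first among ties
    order = np.argsort(-arr, kind="stable")[:k]
    return arr[order]


def t_test(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> TestResult:
    """Welch's two-sided unequal-variance t-test on means.

    When both samples are constant with equal means the test is degenerate
    and p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, a.size, b.size, "welch_t")
        raise ValueError("zero variance in both samples with unequal means")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(stat), float(p), a.size, b.size, "welch_t")


def ks_normality(values: Sequence[float] | np.ndarray) -> TestResult:
    """One-sample KS test against a normal with the sample mean and SD.

    The p-value is approximate because the parameters are estimated from the
    same sample (Lilliefors situation).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ValueError("need at least 5 observations")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = sps.kstest(arr, "norm", args=(arr.mean(), sd))
    return TestResult(float(stat), float(p), arr.size, 0, "ks_normality_approx")


def per_protein_disorder(proteins, min_length: int = 41) -> np.ndarray:
    """Percent of residues in disordered regions >= min_length, per protein."""
    out = np.empty(len(proteins), dtype=float)
    for i, prot in enumerate(proteins):
        runs = disordered_run_lengths(prot.labels)
        out[i] = 100.0 * runs[runs >= min_length].sum() / prot.length
    return out


def compare_categories(
    dataset: Dataset,
    organisms_a: Sequence[str],
    organisms_b: Sequence[str],
    group: str = "Cp",
    min_length: int = 41,
    fraction: float = 0.25,
) -> TestResult:
    """Compare disorder of one functional group between two organism sets.

    Pipeline: per-protein percent of residues in disordered regions of
    length >= ``min_length``, reduced to the top ``fraction`` most disordered
    proteins per side, then Welch's t-test.
    """
    vals = []
    for oids in (organisms_a, organisms_b):
        members = proteins_in_group(dataset.proteins_of(oids), group)
        if not members:
            raise ValueError(f"no proteins in group {group!r} for one partition")
        vals.append(top_fraction(per_protein_disorder(members, min_length), fraction))
    return t_test(vals[0], vals[1])


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the pipeline)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
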