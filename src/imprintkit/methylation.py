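"""Bisulfite clone summaries, allelic-expression quantification, and the
small statistical tests used alongside them.

Bisulfite clones carry one CpG call string each (``M`` methylated, ``U``
unmethylated, ``N`` no call) plus non-CpG conversion counts for QC: an
incompletely converted clone (unconverted non-CpG cytosines) would inflate
apparent methylation, so clones below a conversion threshold are excluded,
as are clones with too few readable CpGs.  Per-clone percent methylation
uses called CpGs only.

Expression quantification follows the comparative-Ct convention
(efficiency^-ddCt, target normalised to a housekeeping assay and expressed
relative to a calibrator sample), and allelic imprinting is summarised as
a maternal:paternal ratio normalised to a biallelic reference condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VALID_CALLS = frozenset("MUN")

ALLELE_MATERNAL = "maternal"
ALLELE_PATERNAL = "paternal"
ALLELE_UNKNOWN = "unknown"


@dataclass(frozen=True)
class BisulfiteClone:
    """One sequenced subclone: an ordered CpG call string plus QC counts."""

    clone_id: str
    amplicon: str
    allele: str
    cpg_calls: str
    noncpg_total: int
    noncpg_unconverted: int

    def __post_init__(self) -> None:
        if not self.cpg_calls:
            raise ValueError("cpg_calls must be non-empty")
        bad = set(self.cpg_calls) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid CpG calls {sorted(bad)} in {self.clone_id}")
        if self.noncpg_total < 0 or not (
            0 <= self.noncpg_unconverted <= max(self.noncpg_total, 0)
        ):
            raise ValueError("invalid non-CpG conversion counts")

    @property
    def conversion_rate(self) -> float | None:
        if self.noncpg_total == 0:
            return None
        return 1.0 - self.noncpg_unconverted / self.noncpg_total

    @property
    def n_called(self) -> int:
        return sum(1 for c in self.cpg_calls if c != "N")


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: str | None = None


def conversion_qc(clone: BisulfiteClone, min_conversion: float = 0.95,
                  min_called_fraction: float = 0.9) -> QcResult:
    """Pass/fail a clone on bisulfite conversion and CpG readability."""
    if clone.noncpg_total == 0:
        return QcResult(False, "no conversion evidence")
    rate = clone.conversion_rate
    if rate < min_conversion:
        return QcResult(False, f"conversion {rate:.3f} < {min_conversion}")
    called_fraction = clone.n_called / len(clone.cpg_calls)
    if called_fraction < min_called_fraction:
        return QcResult(
            False, f"called fraction {called_fraction:.3f} < {min_called_fraction}"
        )
    return QcResult(True)


def clone_percent_methylation(clone: BisulfiteClone) -> float:
    """100 * #M / (#M + #U); no-calls are excluded from the denominator."""
    n_m = clone.cpg_calls.count("M")
    n_u = clone.cpg_calls.count("U")
    if n_m + n_u == 0:
        raise ValueError(f"clone {clone.clone_id} has no called CpGs")
    return 100.0 * n_m / (n_m + n_u)


@dataclass
class MethylationSummary:
    n_clones_pass: int
    n_clones_fail: int
    per_clone_pct: list[float]
    mean_pct: float
    min_pct: float
    max_pct: float
    per_cpg_fraction: np.ndarray
    qc_reasons: list[str] = field(default_factory=list)


def summarize_allele(clones: Sequence[BisulfiteClone],
                     min_conversion: float = 0.95,
                     min_called_fraction: float = 0.9) -> MethylationSummary:
    """QC then summarise per-clone and per-CpG methylation for one allele."""
    passing: list[BisulfiteClone] = []
    reasons: list[str] = []
    for clone in clones:
        qc = conversion_qc(clone, min_conversion, min_called_fraction)
        if qc.passed:
            passing.append(clone)
        else:
            reasons.append(f"{clone.clone_id}: {qc.reason}")
    if not passing:
        raise ValueError("no clones passed QC")

    pcts = [clone_percent_methylation(c) for c in passing]

    n_cpgs = max(len(c.cpg_calls) for c in passing)
    meth = np.zeros(n_cpgs)
    called = np.zeros(n_cpgs)
    for c in passing:
        for i, call in enumerate(c.cpg_calls):
            if call == "M":
                meth[i] += 1
                called[i] += 1
            elif call == "U":
                called[i] += 1
    with np.errstate(invalid="ignore"):
        per_cpg = np.where(called > 0, meth / np.maximum(called, 1), np.nan)

    return MethylationSummary(
        n_clones_pass=len(passing),
        n_clones_fail=len(reasons),
        per_clone_pct=pcts,
        mean_pct=float(np.mean(pcts)),
        min_pct=float(np.min(pcts)),
        max_pct=float(np.max(pcts)),
        per_cpg_fraction=per_cpg,
        qc_reasons=reasons,
    )


def read_clone_table(path: str | Path) -> list[BisulfiteClone]:
    """Clone TSV: clone_id, amplicon, allele, cpg_calls, nonCpG_total, nonCpG_unconverted."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"cpg_calls": str})
    return [
        BisulfiteClone(
            str(r.clone_id), str(r.amplicon), str(r.allele), str(r.cpg_calls),
            int(r.nonCpG_total), int(r.nonCpG_unconverted),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Band ratios and qPCR quantification
# ---------------------------------------------------------------------------

def band_ratio(methylated_signal: float, unmethylated_signal: float) -> float:
    """Methylated:unmethylated band intensity ratio from a blot."""
    if unmethylated_signal <= 0:
        raise ValueError("unmethylated signal must be positive")
    if methylated_signal < 0:
        raise ValueError("methylated signal must be non-negative")
    return methylated_signal / unmethylated_signal


def relative_quantity(ct_target: float, ct_normalizer: float,
                      ct_target_cal: float, ct_normalizer_cal: float,
                      efficiency: float = 2.0) -> float:
    """Comparative-Ct relative expression as percent of the calibrator.

    ``100 * efficiency**(-ddCt)`` with
    ``ddCt = (ct_target - ct_normalizer) - (ct_target_cal - ct_normalizer_cal)``.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency must be in (1, 2]")
    ddct = (ct_target - ct_normalizer) - (ct_target_cal - ct_normalizer_cal)
    return 100.0 * efficiency ** (-ddct)


@dataclass(frozen=True)
class AllelicQuantification:
    sample: str
    maternal_qty: float
    paternal_qty: float
    ratio: float
    normalized_ratio: float


def allelic_ratio(mat_qty: float, pat_qty: float,
                  reference_ratio: float = 1.0) -> float:
    """Maternal:paternal expression ratio normalised to a reference condition.

    The reference is conventionally a biallelic condition whose ratio is
    set to 1, so the returned value reads as fold-maternal-bias relative
    to biallelic expression.
    """
    if mat_qty <= 0 or pat_qty <= 0 or reference_ratio <= 0:
        raise ValueError("quantities and reference ratio must be positive")
    return (mat_qty / pat_qty) / reference_ratio


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------

def p_to_stars(p: float) -> str:
    """Conventional star mapping: *** <0.001, ** <0.01, * <0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    stars: str


def ttest_unpaired(group_a: Sequence[float], group_b: Sequence[float],
                   equal_variance: bool = True) -> TTestResult:
    """Two-sided unpaired t-test (Student by default, Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("both groups constant and equal; t set to 0, p to 1")
            df = a.size + b.size - 2 if equal_variance else float(a.size + b.size - 2)
            return TTestResult(0.0, float(df), 1.0, "ns")
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return TTestResult(
        float(res.statistic), float(res.df), float(res.pvalue),
        p_to_stars(float(res.pvalue)),
    )


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype class counts with expected segregation weights."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    expected_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.counts) == len(self.expected_weights)):
            raise ValueError("labels, counts and weights must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if any(w <= 0 for w in self.expected_weights):
            raise ValueError("expected weights must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


def genotype_ratio_test(counts: GenotypeCounts) -> ChiSquareResult:
    """Pearson chi-square goodness of fit against the expected weights.

    Used to check Mendelian segregation, e.g. observed litter counts
    against a 1:2:1 expectation from a heterozygote intercross.
    """
    total = counts.total
    if total == 0:
        raise ValueError("total count must be positive")
    weights = np.asarray(counts.expected_weights, dtype=float)
    expected = total * weights / weights.sum()
    if np.any(expected == 0):
        raise ValueError("expected counts must be positive")
    res = stats.chisquare(np.asarray(counts.counts, dtype=float), expected)
    return ChiSquareResult(
        float(res.statistic), len(counts.counts) - 1, float(res.pvalue)
    )


def read_genotype_table(path: str | Path,
                        weights: Sequence[float] | None = None) -> GenotypeCounts:
    """Genotype TSV with columns ``genotype`` (per animal) or ``genotype,count``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "count" in df.columns:
        labels = tuple(str(g) for g in df["genotype"])
        counts = tuple(int(c) for c in df["count"])
    else:
        vc = df["genotype"].value_counts()
        labels = tuple(str(g) for g in vc.index)
        counts = tuple(int(c) for c in vc.values)
    if weights is None:
        weights = tuple(1.0 for _ in labels)
    return GenotypeCounts(labels, counts, tuple(float(w) for w in weights))
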