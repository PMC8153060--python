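"""Across-subject structural covariance networks.

Structural covariance asks which brain regions co-vary with a seed region
(here: the claustrum) across subjects in a structural measure — regional
volume, T1w/T2w ratio, or mean diffusivity. Because subject-specific global
biases (head size, semiquantitative image scaling) inflate correlations
everywhere, each subject's row of regional values is first standardized to a
z-score across regions; Pearson correlations are then taken across subjects
between the seed's standardized values and every other region's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CovarianceError

#: Minimum number of complete subject pairs for a correlation to be computed.
MIN_PAIRS = 3


def _split_label(label: str) -> tuple[str, str]:
    """'insula.L' -> ('insula', 'left'); unsuffixed labels get hemisphere ''."""
    if label.endswith(".L"):
        return label[:-2], "left"
    if label.endswith(".R"):
        return label[:-2], "right"
    return label, ""


@dataclass
class RegionMeasureTable:
    """Subjects x regions matrix of one structural measure.

    ``values`` is a DataFrame indexed by subject identifier with one column
    per region label (hemisphere-tagged with a .L/.R suffix). The reference
    design has 80 regions (40 per hemisphere: 35 cortical + 5 subcortical),
    but any number >= 2 is accepted.
    """

    values: pd.DataFrame
    measure: str = "volume"
    units: str = "mm^3"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise CovarianceError(f"duplicate region labels: {dups}")
        if self.values.shape[1] < 2:
            raise CovarianceError("need at least 2 regions")
        self.values = self.values.astype(float)

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_csv(cls, path, measure: str = "volume", units: str = "", sep=None) -> "RegionMeasureTable":
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        return cls(df, measure=measure, units=units)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="subject")


def zscore_across_regions(table: RegionMeasureTable) -> RegionMeasureTable:
    """Standardize each subject's row across regions.

    Row-wise (x - mean) / sd with the sample (n-1) convention, over finite
    entries. This removes per-subject additive and multiplicative biases
    (which shift or scale a whole row) before correlating across subjects.
    A constant row is an error naming the subject.
    """
    vals = table.values
    out = vals.copy()
    for subject, row in vals.iterrows():
        finite = row[np.isfinite(row)]
        if finite.nunique() < 2:
            raise CovarianceError(
                f"subject {subject!r}: row is constant (or has <2 finite values); "
                "z-score across regions is undefined"
            )
        out.loc[subject] = (row - finite.mean()) / finite.std(ddof=1)
    return RegionMeasureTable(out, measure=table.measure, units=f"z({table.units})")


@dataclass
class CovarianceResult:
    """Seed-region covariance network: per-region r, p, effective n, flags."""

    seed: str
    table: pd.DataFrame  # columns: region, hemisphere, r, p, n, significant
    measure: str = ""
    alpha: float = float("nan")
    n_tests: int = 0
    method: str = ""

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "measure": self.measure,
                    "alpha": self.alpha,
                    "n_tests": self.n_tests,
                    "method": self.method,
                },
                fh,
                indent=2,
            )


def covariance_network(
    table: RegionMeasureTable, seed: str, standardize: bool = True
) -> CovarianceResult:
    """Pearson correlation across subjects between the seed and every other region.

    The seed's own column is excluded; the contralateral homologue is an
    ordinary target. Missing values are handled pairwise-complete with the
    effective n reported per region; regions with fewer than 3 complete
    pairs get r = NaN and are flagged in the ``n`` column. By default the
    table is (re-)standardized across regions per subject first — Pearson r
    is affine-invariant per column, so standardization only matters through
    its removal of cross-subject bias.
    """
    if seed not in table.regions:
        raise CovarianceError(f"seed region {seed!r} not in table")
    if len(table.subjects) < MIN_PAIRS:
        raise CovarianceError(f"need at least {MIN_PAIRS} subjects, got {len(table.subjects)}")
    work = zscore_across_regions(table) if standardize else table
    x = work.values[seed].to_numpy()
    rows = []
    for region in work.regions:
        if region == seed:
            continue
        y = work.values[region].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < MIN_PAIRS:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
        name, hemi = _split_label(region)
        rows.append(
            {"region": name, "hemisphere": hemi, "r": float(r), "p": float(p),
             "n": n, "significant": False}
        )
    return CovarianceResult(
        seed=seed, table=pd.DataFrame(rows), measure=table.measure
    )


def default_n_tests(n_target_regions: int, n_measures: int = 3, n_hemispheres: int = 2) -> int:
    """Family size for the correction: hemispheres x target regions x measures.

    Matches the scheme of running the seed network once per hemisphere and
    once per structural measure and correcting over the whole family.
    """
    return n_hemispheres * n_target_regions * n_measures


def correct_significance(
    result: CovarianceResult,
    alpha: float = 0.01,
    n_tests: int | None = None,
    method: str = "bonferroni",
    n_measures: int = 3,
) -> CovarianceResult:
    """Flag regions surviving multiple-comparison correction.

    Bonferroni (default, the strictest defensible reading of "corrected"):
    significant iff p < alpha / n_tests. ``n_tests`` defaults to
    ``default_n_tests`` computed from the actual number of target regions.
    ``method="fdr_bh"`` applies Benjamini-Hochberg over this result's
    p-values instead.
    """
    if not 0 < alpha < 1:
        raise CovarianceError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests is None:
        n_tests = default_n_tests(len(result.table), n_measures=n_measures)
    if n_tests < 1:
        raise CovarianceError("n_tests must be >= 1")
    tab = result.table.copy()
    pvals = tab["p"].to_numpy()
    finite = np.isfinite(pvals)
    sig = np.zeros(len(tab), dtype=bool)
    if method == "bonferroni":
        sig[finite] = pvals[finite] < alpha / n_tests
    elif method == "fdr_bh":
        if finite.any():
            sig[finite] = multipletests(pvals[finite], alpha=alpha, method="fdr_bh")[0]
    else:
        raise CovarianceError(f"unknown correction method {method!r}")
    tab["significant"] = sig
    return replace(result, table=tab, alpha=alpha, n_tests=int(n_tests), method=method)
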