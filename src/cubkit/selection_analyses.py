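"""Mutation-vs-selection diagnostics on per-gene CUB profiles.

Three classic plots drive the inference, all computed here without any
plotting dependency:

* **ENc-GC3s**: observed ENc against the curve expected when bias is set by
  third-position base composition alone; genes well below the curve point to
  selection on codon choice.
* **PR2 bias**: within-strand purine/pyrimidine balance at synonymous third
  positions; (0.5, 0.5) is the mutation-drift equilibrium point.
* **Neutrality regression**: GC12 on GC3 across genes; a slope near 1 means
  directional mutation pressure moves all codon positions together, a slope
  near 0 means third positions are decoupled (selection).

Also here: the pairwise index correlation matrix with significance stars and
the ENc-expression (FPKM) correlation.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import CodonCountTable
from .cub_indices import CUBProfile, profile_frame
from .errors import EmptyInputError, UndefinedMetricError
from .genetic_code import GeneticCode, standard_code

log = logging.getLogger(__name__)

#: ENc at or below this marks strong codon usage bias.
STRONG_BIAS_ENC = 35.0
#: ENc in [50, 61] marks weak bias.
WEAK_BIAS_ENC = 50.0


def expected_enc(gc3s: float) -> float:
    """Expected ENc under pure mutation pressure at a given GC3s.

    ENc* = 2 + s + 29 / (s^2 + (1 - s)^2) with s = GC3s in [0, 1].
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s ** 2 + (1.0 - gc3s) ** 2)


@dataclass
class EncGc3sPoint:
    gene_id: str
    gc3s: float
    enc_observed: float
    enc_expected: float
    residual: float            # expected - observed; positive = below curve
    position: Literal["above", "on", "below"]
    bias_class: Literal["strong", "intermediate", "weak"]


@dataclass
class EncGc3sSummary:
    n: int
    n_strong: int
    n_intermediate: int
    n_weak: int
    pct_strong: float
    pct_weak: float
    n_below_curve: int
    n_on_curve: int
    n_above_curve: int


def classify_bias(enc_value: float) -> str:
    """Bias strength from ENc: strong (<=35), weak (50-61), else intermediate."""
    if enc_value <= STRONG_BIAS_ENC:
        return "strong"
    if enc_value >= WEAK_BIAS_ENC:
        return "weak"
    return "intermediate"


def _as_frame(profiles: Sequence[CUBProfile] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profile_frame(list(profiles))


def enc_gc3s_analysis(
    profiles: Sequence[CUBProfile] | pd.DataFrame,
    tolerance: float = 0.5,
) -> tuple[list[EncGc3sPoint], EncGc3sSummary]:
    """Place every gene relative to the expected ENc curve and tally classes.

    ``tolerance`` (ENc units) defines the "on the curve" band; it is purely
    presentational and does not affect the bias-class tallies.
    """
    df = _as_frame(profiles)
    df = df[df["enc"].notna()]
    if df.empty:
        raise EmptyInputError("enc_gc3s_analysis requires at least one defined ENc")
    points: list[EncGc3sPoint] = []
    for gene_id, row in df.iterrows():
        exp = expected_enc(float(row["gc3s"]))
        resid = exp - float(row["enc"])
        if abs(resid) <= tolerance:
            position = "on"
        elif resid > 0:
            position = "below"
        else:
            position = "above"
        points.append(EncGc3sPoint(
            gene_id=str(gene_id),
            gc3s=float(row["gc3s"]),
            enc_observed=float(row["enc"]),
            enc_expected=exp,
            residual=resid,
            position=position,
            bias_class=classify_bias(float(row["enc"])),
        ))
    n = len(points)
    n_strong = sum(p.bias_class == "strong" for p in points)
    n_weak = sum(p.bias_class == "weak" for p in points)
    summary = EncGc3sSummary(
        n=n,
        n_strong=n_strong,
        n_intermediate=n - n_strong - n_weak,
        n_weak=n_weak,
        pct_strong=100.0 * n_strong / n,
        pct_weak=100.0 * n_weak / n,
        n_below_curve=sum(p.position == "below" for p in points),
        n_on_curve=sum(p.position == "on" for p in points),
        n_above_curve=sum(p.position == "above" for p in points),
    )
    return points, summary


@dataclass
class PR2Point:
    """Parity-rule-2 coordinates: x = G3/(G3+C3), y = A3/(A3+T3)."""

    gene_id: str
    x: float
    y: float

    @property
    def quadrant(self) -> str:
        """Quadrant relative to the (0.5, 0.5) parity point."""
        horiz = "right" if self.x > 0.5 else ("left" if self.x < 0.5 else "center")
        vert = "upper" if self.y > 0.5 else ("lower" if self.y < 0.5 else "center")
        return f"{vert}-{horiz}"


def pr2_point(
    counts: CodonCountTable,
    scope: Literal["all_synonymous", "fourfold_only"] = "all_synonymous",
    code: GeneticCode | None = None,
) -> PR2Point:
    """Third-position base parity of one gene.

    ``scope`` selects which codons contribute third-position bases: every
    synonymous codon (default) or only the fourfold-degenerate families
    (classic Sueoka formulation, where all four bases are silent).
    """
    code = code or standard_code()
    third = {b: 0 for b in "ACGT"}
    for aa, family in code.degenerate_families.items():
        if scope == "fourfold_only" and len(family) != 4:
            continue
        for c in family:
            third[c[2]] += counts[c]
    at = third["A"] + third["T"]
    gc = third["G"] + third["C"]
    if at == 0 or gc == 0:
        raise UndefinedMetricError(
            f"{counts.gene_id}: PR2 undefined (A3+T3={at}, G3+C3={gc})"
        )
    return PR2Point(
        gene_id=counts.gene_id,
        x=third["G"] / gc,
        y=third["A"] / at,
    )


@dataclass
class RegressionResult:
    """OLS fit y ~ x with the mutation/selection decomposition of the slope."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int

    @property
    def mutation_pct(self) -> float:
        return self.slope * 100.0

    @property
    def selection_pct(self) -> float:
        return (1.0 - self.slope) * 100.0


def _regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if len(x) < 3:
        raise EmptyInputError("regression requires at least 3 points")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("zero variance in predictor")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(x),
    )


def neutrality_regression(profiles: Sequence[CUBProfile] | pd.DataFrame) -> RegressionResult:
    """Neutrality plot regression: GC12 ~ GC3 over genes.

    slope*100 is read as the percent contribution of mutation pressure,
    (1-slope)*100 as that of selection.
    """
    df = _as_frame(profiles)
    return _regress(df["gc3"].to_numpy(float), df["gc12"].to_numpy(float))


@dataclass
class CorrelationMatrix:
    indices: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame


def significance_stars(p: float) -> str:
    """Conventional tiers: * p<0.05, ** p<0.01, *** p<0.001."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(
    profiles: Sequence[CUBProfile] | pd.DataFrame,
    indices: Sequence[str] = ("enc", "cai", "cbi", "fop", "gc", "gc1", "gc2", "gc3",
                              "gc3s", "a3s", "t3s", "g3s", "c3s"),
) -> CorrelationMatrix:
    """Pairwise Pearson correlations between index columns, with stars.

    Constant columns yield NaN cells (undefined correlation), flagged by an
    empty star string.
    """
    df = _as_frame(profiles)
    if len(df) < 3:
        raise EmptyInputError("correlation_matrix requires at least 3 genes")
    cols = list(indices)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        xa = df[a].to_numpy(float)
        xb = df[b].to_numpy(float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        rv, pv = stats.pearsonr(xa, xb)
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    stars = p.map(significance_stars)
    return CorrelationMatrix(indices=cols, r=r, p=p, stars=stars)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-format expression table (gene_id, condition, fpkm) into a
    wide gene x condition FPKM DataFrame."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.pivot_table(index="gene_id", columns="condition", values="fpkm")


def expression_correlation(
    profiles: Sequence[CUBProfile] | pd.DataFrame,
    expression: pd.DataFrame | Mapping[str, Mapping[str, float]],
    total_label: str = "total",
) -> dict[str, RegressionResult]:
    """Per-condition regression of FPKM on ENc, plus a pooled 'total'.

    ``expression`` is a gene x condition FPKM table; the 'total' condition is
    its row sum. Both the Pearson r and the OLS slope are reported per
    condition (published "correlations" below -1 are recognisable as slopes).
    Genes missing from either table are dropped pairwise and logged.
    """
    df = _as_frame(profiles)
    expr = pd.DataFrame(expression).copy()
    if total_label not in expr.columns:
        expr[total_label] = expr.sum(axis=1)
    common = df.index.intersection(expr.index)
    missing = df.index.difference(expr.index)
    if len(missing):
        log.warning("expression missing for %d genes (pairwise-complete)", len(missing))
    out: dict[str, RegressionResult] = {}
    for cond in expr.columns:
        sub = pd.concat([df.loc[common, "enc"], expr.loc[common, cond]], axis=1).dropna()
        out[str(cond)] = _regress(sub["enc"].to_numpy(float), sub[cond].to_numpy(float))
    return out
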