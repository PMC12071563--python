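"""Reader-agreement statistics for ordinal mitotic scores.

The clinical question is whether two readers (or a reader and an expert
consensus) assign the same mitotic score 1/2/3, and whether they count in
the same place. Four statistics cover it:

* accuracy — proportion of slides where a reader's score matches consensus;
* linear weighted Cohen's kappa — chance-corrected ordinal agreement with
  disagreement penalty |i − j| / (k − 1), with a 95% CI;
* ICC(2,1) — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation, with an F-based 95% CI;
* zone intersection rate — proportion of slides on which the two selected
  circular counting zones overlap (tangency inclusive).

Weighted kappa and its asymptotic CI come from statsmodels; the ICC and its
CI from pingouin. A bootstrap kappa CI is available as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from statsmodels.stats.inter_rater import cohens_kappa

from .geometry import CircleZone, PointUm, circles_intersect

__all__ = [
    "LABELS",
    "ConfusionMatrix3",
    "KappaResult",
    "ICCResult",
    "AgreementReport",
    "accuracy",
    "kappa_linear",
    "icc_scores",
    "zone_intersection_rate",
    "ai_zone_intersection_rate",
    "subgroup_report",
]

LABELS = (1, 2, 3)

#: Sentinel for a slide where a reader explicitly recorded "no zone";
#: distinct from a missing entry, which is excluded from the denominator.
NO_ZONE = "no_zone"


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3×3 contingency table of paired ordinal scores.

    Rows are rater A (by convention the investigator), columns rater B (the
    consensus or the second investigator); labels are scores 1..3.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError(f"expected a 3x3 table, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(float))

    @classmethod
    def from_pairs(
        cls, a: Sequence[int], b: Sequence[int]
    ) -> "ConfusionMatrix3":
        a = np.asarray(a, dtype=int)
        b = np.asarray(b, dtype=int)
        if a.shape != b.shape:
            raise ValueError("paired score vectors must have equal length")
        if not (np.isin(a, LABELS).all() and np.isin(b, LABELS).all()):
            raise ValueError("scores must be in {1, 2, 3}")
        counts = np.zeros((3, 3))
        for i, j in zip(a, b):
            counts[i - 1, j - 1] += 1
        return cls(counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def transpose(self) -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts.T)


def _as_matrix(x) -> ConfusionMatrix3:
    if isinstance(x, ConfusionMatrix3):
        return x
    if isinstance(x, tuple) and len(x) == 2:
        return ConfusionMatrix3.from_pairs(*x)
    return ConfusionMatrix3(np.asarray(x))


def accuracy(x) -> float:
    """Proportion of exact score matches: trace / total.

    Accepts a ConfusionMatrix3, a raw 3×3 array, or a (scores_a, scores_b)
    pair of vectors.
    """
    cm = _as_matrix(x)
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty table")
    return float(np.trace(cm.counts) / cm.total)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float
    n: float
    method: str = "asymptotic"

    def __str__(self) -> str:
        return (
            f"kappa_w = {self.kappa:.3f} "
            f"(95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}], n = {self.n:g})"
        )


def kappa_linear(
    x, ci: str = "asymptotic", n_boot: int = 2000, seed: int | None = None
) -> KappaResult:
    """Linear weighted Cohen's kappa with a 95% confidence interval.

    κ_w = 1 − Σ w_ij p_ij / Σ w_ij e_ij with disagreement weights
    w_ij = |i − j| / (k − 1) and e_ij the product of marginals. The default
    CI uses the standard asymptotic variance of weighted kappa
    (statsmodels); ``ci="bootstrap"`` resamples the pairs instead.

    Raises if either rater's marginal puts all mass in one category — kappa
    is undefined there, and silently reporting 0 would hide it.
    """
    cm = _as_matrix(x)
    if cm.total < 2:
        raise ValueError("kappa requires at least 2 paired observations")
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    if (row > 0).sum() < 2 or (col > 0).sum() < 2:
        raise ValueError(
            "kappa undefined: a rater used a single category (degenerate marginal)"
        )
    res = cohens_kappa(cm.counts, wt="linear")
    k = float(res.kappa)
    if ci == "asymptotic":
        return KappaResult(
            kappa=k,
            ci_low=float(res.kappa_low),
            ci_high=float(res.kappa_upp),
            se=float(np.sqrt(res.var_kappa)),
            n=cm.total,
        )
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        pairs = [
            (i, j)
            for i in range(3)
            for j in range(3)
            for _ in range(int(round(cm.counts[i, j])))
        ]
        pairs = np.asarray(pairs)
        stats = []
        for _ in range(n_boot):
            samp = pairs[rng.integers(0, len(pairs), len(pairs))]
            t = np.zeros((3, 3))
            np.add.at(t, (samp[:, 0], samp[:, 1]), 1)
            r, c = t.sum(axis=1), t.sum(axis=0)
            if (r > 0).sum() < 2 or (c > 0).sum() < 2:
                continue
            stats.append(float(cohens_kappa(t, wt="linear").kappa))
        lo, hi = np.percentile(stats, [2.5, 97.5])
        return KappaResult(
            kappa=k,
            ci_low=float(lo),
            ci_high=float(hi),
            se=float(np.std(stats, ddof=1)),
            n=cm.total,
            method="bootstrap",
        )
    raise ValueError(f"unknown CI method {ci!r}")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    form: str
    n_subjects: int

    def __str__(self) -> str:
        return (
            f"{self.form} = {self.icc:.3f} "
            f"(95% CI [{self.ci_low:.3f}, {self.ci_high:.3f}], "
            f"n = {self.n_subjects})"
        )


# map the conventional Shrout-Fleiss names to pingouin's type labels:
# ICC2 = two-way random, absolute agreement, single rater = ICC(A,1)
_ICC_FORMS = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
              "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)"}


def icc_scores(
    ratings_a: Sequence[float],
    ratings_b: Sequence[float],
    form: str = "ICC2",
) -> ICCResult:
    """Intraclass correlation between two raters' aligned rating vectors.

    The default form, ICC2 (a.k.a. ICC(2,1)): two-way random effects,
    absolute agreement, single rater — the reliability of one rater's score
    when raters are a random sample. Alternate forms are accepted so a
    reported value of unknown provenance can be checked against each.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two aligned 1-D vectors")
    n = len(a)
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    if form not in _ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}")
    stacked = np.concatenate([a, b])
    if np.allclose(stacked.var(), 0):
        raise ValueError("ICC undefined: zero total variance")
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "rating": stacked,
        }
    )
    with warnings.catch_warnings():
        # degenerate sub-forms (e.g. zero error MS under perfect agreement)
        # warn inside pingouin; the requested form is still well defined
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            table = pg.intraclass_corr(
                data=df, targets="subject", raters="rater", ratings="rating"
            )
        except AssertionError as e:  # estimator's own minimum-size checks
            raise ValueError(f"ICC undefined: {e}") from None
    # pingouin labels ICC(2,1) as ICC2 / "Single random raters"
    row = table.loc[table["Type"] == _ICC_FORMS[form]].iloc[0]
    est = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    if not math.isfinite(est):
        raise ValueError("ICC undefined for this data (no between-subject variance)")
    return ICCResult(icc=est, ci_low=lo, ci_high=hi, form=form, n_subjects=n)


def zone_intersection_rate(
    zones_a: Mapping[str, CircleZone | str],
    zones_b: Mapping[str, CircleZone | str],
) -> tuple[float, dict[str, bool], list[str]]:
    """Spatial agreement of counting-zone selection.

    Returns (rate, per-slide flags, excluded slide ids). A slide enters the
    denominator when both readers supply an entry; an entry may be the
    NO_ZONE sentinel ("no zone recorded"), which counts as non-intersecting.
    Slides present for only one reader are excluded and listed.
    """
    common = sorted(set(zones_a) & set(zones_b))
    excluded = sorted(set(zones_a) ^ set(zones_b))
    if not common:
        raise ValueError("no slides with zones from both readers")
    flags: dict[str, bool] = {}
    for sid in common:
        za, zb = zones_a[sid], zones_b[sid]
        if za == NO_ZONE or zb == NO_ZONE:
            flags[sid] = False
        else:
            flags[sid] = circles_intersect(za, zb)
    rate = sum(flags.values()) / len(flags)
    return rate, flags, excluded


def ai_zone_intersection_rate(
    ai_zones: Mapping[str, Sequence[CircleZone]],
    reader_zones: Mapping[str, CircleZone | str],
) -> tuple[float, dict[str, bool], list[str]]:
    """Proportion of slides where any AI hotspot zone overlaps the reader's.

    The AI side contributes all its selected display zones; the slide is
    flagged intersecting if at least one overlaps the reader's zone.
    """
    common = sorted(set(ai_zones) & set(reader_zones))
    excluded = sorted(set(ai_zones) ^ set(reader_zones))
    if not common:
        raise ValueError("no slides with both AI and reader zones")
    flags: dict[str, bool] = {}
    for sid in common:
        rz = reader_zones[sid]
        if rz == NO_ZONE or not ai_zones[sid]:
            flags[sid] = False
        else:
            flags[sid] = any(circles_intersect(z, rz) for z in ai_zones[sid])
    rate = sum(flags.values()) / len(flags)
    return rate, flags, excluded


@dataclass(frozen=True)
class AgreementReport:
    """Agreement statistics for one stratum × condition.

    Statistics that are undefined on the stratum (too few slides, degenerate
    marginals, zero variance) are None; n_slides is always reported.
    """

    stratum: str
    condition: str
    n_slides: int
    accuracy: float | None = None
    accuracy_by_reader: dict[str, float] = field(default_factory=dict)
    kappa: KappaResult | None = None
    icc: ICCResult | None = None
    zone_intersection_rate: float | None = None
    notes: tuple[str, ...] = ()

    def to_row(self) -> dict:
        return {
            "stratum": self.stratum,
            "condition": self.condition,
            "n_slides": self.n_slides,
            "accuracy": self.accuracy,
            "kappa": None if self.kappa is None else self.kappa.kappa,
            "kappa_ci_low": None if self.kappa is None else self.kappa.ci_low,
            "kappa_ci_high": None if self.kappa is None else self.kappa.ci_high,
            "icc": None if self.icc is None else self.icc.icc,
            "icc_ci_low": None if self.icc is None else self.icc.ci_low,
            "icc_ci_high": None if self.icc is None else self.icc.ci_high,
            "zone_intersection_rate": self.zone_intersection_rate,
            "notes": "; ".join(self.notes),
        }

    def summary(self) -> str:
        lines = [f"[{self.stratum} | {self.condition}]  n = {self.n_slides}"]
        if self.accuracy is not None:
            lines.append(f"  accuracy vs consensus : {self.accuracy:.3f}")
        for rid, acc in sorted(self.accuracy_by_reader.items()):
            lines.append(f"    reader {rid:<12}: {acc:.3f}")
        if self.kappa is not None:
            lines.append(f"  inter-reader {self.kappa}")
        if self.icc is not None:
            lines.append(f"  inter-reader {self.icc}")
        if self.zone_intersection_rate is not None:
            lines.append(
                f"  zone intersection rate: {self.zone_intersection_rate:.3f}"
            )
        for note in self.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)


def _records_zones(sub: pd.DataFrame) -> dict[str, CircleZone | str]:
    zones: dict[str, CircleZone | str] = {}
    for _, r in sub.iterrows():
        if "zone_x" not in r or pd.isna(r.get("zone_x")):
            continue
        if r.get("zone_x") == NO_ZONE:
            zones[r["slide_id"]] = NO_ZONE
        else:
            zones[r["slide_id"]] = CircleZone(
                center=PointUm(float(r["zone_x"]), float(r["zone_y"])),
                radius_um=float(r["zone_radius_um"]),
            )
    return zones


def _stratum_report(
    sub: pd.DataFrame, consensus: Mapping[str, int], stratum: str, condition: str
) -> AgreementReport:
    readers = sorted(sub["reader_id"].unique())
    slides = sorted(sub["slide_id"].unique())
    n = len(slides)
    notes: list[str] = []
    if n < 2:
        return AgreementReport(
            stratum=stratum, condition=condition, n_slides=n,
            notes=("fewer than 2 slides; statistics undefined",),
        )

    # accuracy vs consensus, pooled and per reader
    merged = sub.assign(truth=sub["slide_id"].map(consensus))
    merged = merged.dropna(subset=["truth"])
    acc = float((merged["score"] == merged["truth"]).mean()) if len(merged) else None
    acc_by = {
        rid: float((g["score"] == g["truth"]).mean())
        for rid, g in merged.groupby("reader_id")
    }

    kappa = icc = zrate = None
    if len(readers) == 2:
        wide = sub.pivot_table(
            index="slide_id", columns="reader_id", values="score", aggfunc="first"
        ).dropna()
        if len(wide) >= 2:
            a = wide[readers[0]].astype(int).to_numpy()
            b = wide[readers[1]].astype(int).to_numpy()
            try:
                kappa = kappa_linear(ConfusionMatrix3.from_pairs(a, b))
            except ValueError as e:
                notes.append(f"kappa: {e}")
            try:
                icc = icc_scores(a, b)
            except ValueError as e:
                notes.append(f"ICC: {e}")
        za = _records_zones(sub[sub["reader_id"] == readers[0]])
        zb = _records_zones(sub[sub["reader_id"] == readers[1]])
        if za and zb and (set(za) & set(zb)):
            zrate, _, _ = zone_intersection_rate(za, zb)
    else:
        notes.append(f"{len(readers)} reader(s); pairwise statistics need exactly 2")

    return AgreementReport(
        stratum=stratum,
        condition=condition,
        n_slides=n,
        accuracy=acc,
        accuracy_by_reader=acc_by,
        kappa=kappa,
        icc=icc,
        zone_intersection_rate=zrate,
        notes=tuple(notes),
    )


def subgroup_report(
    records: pd.DataFrame,
    consensus: Mapping[str, int] | pd.DataFrame,
) -> list[AgreementReport]:
    """Agreement reports overall and per stratum, for each condition.

    records: one row per (slide, reader, condition) with columns slide_id,
    reader_id, condition, score, and optionally specimen_type and
    zone_x/zone_y/zone_radius_um. consensus maps slide_id to the expert
    consensus score (a DataFrame with those two columns is accepted).

    Strata: 'all', each consensus score ('score=1'..'score=3'), and each
    specimen type when the column is present.
    """
    if isinstance(consensus, pd.DataFrame):
        consensus = dict(zip(consensus["slide_id"], consensus["score"].astype(int)))
    required = {"slide_id", "reader_id", "condition", "score"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    strata: list[tuple[str, pd.DataFrame]] = [("all", records)]
    for s in (1, 2, 3):
        slides = {sid for sid, sc in consensus.items() if sc == s}
        strata.append((f"score={s}", records[records["slide_id"].isin(slides)]))
    if "specimen_type" in records.columns and records["specimen_type"].notna().any():
        for spec_type, g in records.groupby("specimen_type"):
            strata.append((f"specimen={spec_type}", g))

    reports = []
    for stratum, sub in strata:
        for condition, csub in sub.groupby("condition"):
            reports.append(_stratum_report(csub, consensus, stratum, str(condition)))
    return reports
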