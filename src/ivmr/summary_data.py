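"""Summary-statistic containers, file I/O, allele harmonization and scale conversion.

Two-sample Mendelian randomization consumes published per-variant association
estimates from two separate studies: one for the exposure (here, serum
gamma-glutamyltransferase, GGT, measured on the natural-log scale) and one for
the outcome (Alzheimer's disease status, on the log-odds scale). This module
provides the record types for those associations, readers for delimited
summary-statistic tables, allele harmonization (aligning both studies to one
effect allele per variant), and the unit conversions the pipeline needs:

* percentage change in the exposure <-> change in its natural log, and
* effect per log-unit of exposure <-> effect per standard deviation (SD),
  using a configurable SD on the log scale (0.65 log-units for serum GGT).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCALE_PERCENT",
    "SCALE_LOG_UNITS",
    "SCALE_LOG_ODDS",
    "SCALE_ODDS_RATIO",
    "FormatError",
    "HarmonizationError",
    "VariantAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "ReadResult",
    "read_associations",
    "read_instruments",
    "write_instruments",
    "percent_to_log",
    "log_to_percent",
    "convert_to_log_scale",
    "harmonize",
    "rescale_per_sd",
]

logger = logging.getLogger(__name__)

#: Effect reported as percentage change in the (untransformed) exposure per allele.
SCALE_PERCENT = "percent-change"
#: Effect reported as change in the natural log of the exposure per allele.
SCALE_LOG_UNITS = "log-units"
#: Effect reported as change in log-odds of a binary outcome per allele.
SCALE_LOG_ODDS = "log-odds"
#: Effect reported as an odds ratio per allele (SE assumed to be SE of the log-OR).
SCALE_ODDS_RATIO = "odds-ratio"

_VALID_SCALES = {SCALE_PERCENT, SCALE_LOG_UNITS, SCALE_LOG_ODDS, SCALE_ODDS_RATIO}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column names expected in delimited summary-statistic files.
DEFAULT_COLUMNS = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "eaf": "eaf",
    "n": "n",
    "p": "p",
}

_REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")


class FormatError(ValueError):
    """A summary-statistics file does not match the expected layout."""


class HarmonizationError(ValueError):
    """Exposure and outcome records cannot be aligned to a common effect allele."""


def _valid_allele(allele: str) -> bool:
    return len(allele) > 0 and all(ch in "ACGT" for ch in allele.upper())


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait association row from a summary-statistics table.

    ``beta`` is the additive per-allele effect of ``effect_allele``; its units
    are given by ``scale``.  ``se`` must be a positive standard error in the
    same units (for ``odds-ratio`` input, ``se`` is taken to be the standard
    error of the log odds ratio, the GWAS reporting convention).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    scale: str
    eaf: float | None = None
    n: float | None = None
    p: float | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {sorted(_VALID_SCALES)}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.rsid}: se must be positive and finite")
        if not (_valid_allele(self.effect_allele) and _valid_allele(self.other_allele)):
            raise ValueError(f"{self.rsid}: alleles must be non-empty strings over A/C/G/T")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie in (0, 1)")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.rsid}: p must lie in (0, 1]")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Per-SNP exposure and outcome effects aligned to one effect allele.

    ``beta_x``/``se_x`` are the per-allele association with the exposure in
    log units; ``beta_y``/``se_y`` the association with the outcome in
    log-odds.  ``flipped`` records that the outcome effect sign was reversed
    during harmonization; ``palindromic`` that the allele pair is A/T or G/C
    (strand-ambiguous).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float | None = None
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.rsid}: standard errors must be positive")


@dataclass
class InstrumentSet:
    """An ordered collection of harmonized instruments plus the exposure SD.

    ``sd_scale`` is the standard deviation of the exposure on the log scale
    (log-units per SD); causal estimates computed on the per-log-unit scale
    are multiplied by it to obtain effects per SD of exposure.
    """

    instruments: list[HarmonizedInstrument]
    sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.instruments) < 1:
            raise ValueError("an InstrumentSet requires at least one instrument")
        if not self.sd_scale > 0:
            raise ValueError("sd_scale must be positive")
        rsids = [inst.rsid for inst in self.instruments]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in instrument set")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def L(self) -> int:
        return len(self.instruments)

    @property
    def rsids(self) -> list[str]:
        return [inst.rsid for inst in self.instruments]

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([inst.beta_x for inst in self.instruments])

    @property
    def se_x(self) -> np.ndarray:
        return np.array([inst.se_x for inst in self.instruments])

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([inst.beta_y for inst in self.instruments])

    @property
    def se_y(self) -> np.ndarray:
        return np.array([inst.se_y for inst in self.instruments])

    @classmethod
    def from_arrays(
        cls,
        beta_x: Sequence[float],
        se_x: Sequence[float],
        beta_y: Sequence[float],
        se_y: Sequence[float],
        rsids: Sequence[str] | None = None,
        eaf: Sequence[float] | None = None,
        sd_scale: float = 1.0,
    ) -> "InstrumentSet":
        """Build a set directly from parallel effect/SE arrays (alleles synthesized)."""
        n = len(beta_x)
        if rsids is None:
            rsids = [f"rs{j + 1}" for j in range(n)]
        instruments = [
            HarmonizedInstrument(
                rsid=str(rsids[j]),
                effect_allele="A",
                other_allele="G",
                beta_x=float(beta_x[j]),
                se_x=float(se_x[j]),
                beta_y=float(beta_y[j]),
                se_y=float(se_y[j]),
                eaf=None if eaf is None else float(eaf[j]),
            )
            for j in range(n)
        ]
        return cls(instruments, sd_scale=sd_scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "effect_allele": [i.effect_allele for i in self.instruments],
                "other_allele": [i.other_allele for i in self.instruments],
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
                "eaf": [i.eaf if i.eaf is not None else np.nan for i in self.instruments],
                "flipped": [i.flipped for i in self.instruments],
                "palindromic": [i.palindromic for i in self.instruments],
            }
        )


@dataclass
class ReadResult:
    """Records parsed from a summary-statistics file plus rejected-row bookkeeping."""

    records: list[VariantAssociation]
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def read_associations(
    path,
    column_map: Mapping[str, str] | None = None,
    scale: str = SCALE_LOG_UNITS,
    trait: str = "",
) -> ReadResult:
    """Read a tab- or comma-delimited association table into records.

    ``column_map`` maps the canonical field names (``rsid``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, and optionally ``eaf``, ``n``, ``p``)
    to the column names actually present in the file.  Rows with missing or
    non-numeric ``beta``/``se`` (or non-positive ``se``) are rejected and
    reported with their 1-based file line number.

    Raises
    ------
    FormatError
        If a mapped required column is absent from the header, or the table
        contains duplicate variant identifiers.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    if scale not in _VALID_SCALES:
        raise ValueError(f"unknown scale {scale!r}")

    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc

    for fieldname in _REQUIRED_FIELDS:
        if colmap[fieldname] not in df.columns:
            raise FormatError(f"{path}: missing required column {colmap[fieldname]!r} (mapped to {fieldname!r})")

    optional_present = {k: colmap[k] in df.columns for k in ("eaf", "n", "p")}

    records: list[VariantAssociation] = []
    rejections: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        raw = dict(zip(df.columns, row))
        beta = pd.to_numeric(raw[colmap["beta"]], errors="coerce")
        se = pd.to_numeric(raw[colmap["se"]], errors="coerce")
        if pd.isna(beta) or pd.isna(se):
            rejections.append((lineno, "missing or non-numeric beta/se"))
            continue
        if not se > 0:
            rejections.append((lineno, f"non-positive se ({se})"))
            continue

        def _opt(key: str) -> float | None:
            if not optional_present[key]:
                return None
            v = pd.to_numeric(raw[colmap[key]], errors="coerce")
            return None if pd.isna(v) else float(v)

        try:
            records.append(
                VariantAssociation(
                    rsid=str(raw[colmap["rsid"]]),
                    effect_allele=str(raw[colmap["effect_allele"]]).upper(),
                    other_allele=str(raw[colmap["other_allele"]]).upper(),
                    beta=float(beta),
                    se=float(se),
                    scale=scale,
                    eaf=_opt("eaf"),
                    n=_opt("n"),
                    p=_opt("p"),
                    trait=trait,
                )
            )
        except ValueError as exc:
            rejections.append((lineno, str(exc)))

    rsids = [r.rsid for r in records]
    dupes = {r for r in rsids if rsids.count(r) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate rsids {sorted(dupes)}")

    if rejections:
        logger.warning("%s: rejected %d of %d data rows", path, len(rejections), len(df))
    return ReadResult(records=records, rejections=rejections)


def percent_to_log(pct: float) -> float:
    """Convert a percentage change in the exposure into a natural-log change.

    A variant raising the exposure by ``pct`` percent multiplies it by
    ``1 + pct/100``, i.e. shifts its natural log by ``ln(1 + pct/100)``.
    """
    if pct <= -100:
        raise ValueError(f"percentage change must exceed -100, got {pct}")
    return math.log1p(pct / 100.0)


def log_to_percent(delta: float) -> float:
    """Convert a natural-log change into a percentage change: ``(e^delta - 1) * 100``."""
    if not math.isfinite(delta):
        raise ValueError(f"log-unit change must be finite, got {delta}")
    return math.expm1(delta) * 100.0


def convert_to_log_scale(records: Iterable[VariantAssociation]) -> list[VariantAssociation]:
    """Convert records onto the additive log scale expected by harmonization.

    ``percent-change`` effects become log-unit effects; the SE is converted by
    the delta method (``se_log = se_pct / (100 + pct)``).  ``odds-ratio``
    effects become log-odds effects (``beta -> ln beta``; SE already refers to
    the log-OR by convention and is left unchanged).  Records already on a log
    scale pass through untouched.
    """
    out: list[VariantAssociation] = []
    for rec in records:
        if rec.scale == SCALE_PERCENT:
            out.append(
                replace(
                    rec,
                    beta=percent_to_log(rec.beta),
                    se=rec.se / (100.0 + rec.beta),
                    scale=SCALE_LOG_UNITS,
                )
            )
        elif rec.scale == SCALE_ODDS_RATIO:
            if rec.beta <= 0:
                raise ValueError(f"{rec.rsid}: odds ratio must be positive")
            out.append(replace(rec, beta=math.log(rec.beta), scale=SCALE_LOG_ODDS))
        else:
            out.append(rec)
    return out


def _is_palindromic(a1: str, a2: str) -> bool:
    pair = {a1, a2}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[ch] for ch in allele)
    except KeyError:
        return None


def harmonize(
    exposure: Iterable[VariantAssociation],
    outcome: Iterable[VariantAssociation],
    palindromic_policy: str = "flag",
    sd_scale: float = 0.65,
) -> InstrumentSet:
    """Align exposure and outcome associations to a common effect allele.

    The instrument list is the intersection of the two tables by rsid, in
    exposure order.  At each shared variant the outcome alleles must either
    match the exposure pair (effect kept as-is) or be its reverse (outcome
    beta sign flipped), optionally after complementing the outcome alleles to
    the opposite strand.  Palindromic variants (A/T, G/C) are handled per
    ``palindromic_policy``: ``"keep"`` retains them silently, ``"flag"``
    retains them with a warning (they are marked in either case), ``"drop"``
    excludes them.

    Exposure records must be on the ``log-units`` scale and outcome records on
    ``log-odds`` (use :func:`convert_to_log_scale` first).
    """
    if palindromic_policy not in {"keep", "drop", "flag"}:
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")

    exposure = list(exposure)
    outcome = list(outcome)
    for rec in exposure:
        if rec.scale != SCALE_LOG_UNITS:
            raise ValueError(f"exposure record {rec.rsid} has scale {rec.scale!r}; convert to log-units first")
    for rec in outcome:
        if rec.scale != SCALE_LOG_ODDS:
            raise ValueError(f"outcome record {rec.rsid} has scale {rec.scale!r}; convert to log-odds first")

    out_by_rsid: dict[str, VariantAssociation] = {}
    for rec in outcome:
        if rec.rsid in out_by_rsid:
            raise HarmonizationError(f"duplicate rsid {rec.rsid} in outcome table")
        out_by_rsid[rec.rsid] = rec

    instruments: list[HarmonizedInstrument] = []
    n_missing = 0
    n_dropped_palindromic = 0
    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            n_missing += 1
            logger.info("harmonize: %s absent from outcome table; excluded", exp.rsid)
            continue

        ea, oa = exp.effect_allele.upper(), exp.other_allele.upper()
        oea, ooa = out.effect_allele.upper(), out.other_allele.upper()

        if (oea, ooa) == (ea, oa):
            flipped = False
        elif (oea, ooa) == (oa, ea):
            flipped = True
        else:
            cea, coa = _complement(oea), _complement(ooa)
            if (cea, coa) == (ea, oa):
                flipped = False
            elif (cea, coa) == (oa, ea):
                flipped = True
            else:
                raise HarmonizationError(
                    f"{exp.rsid}: outcome alleles {oea}/{ooa} neither match nor reverse "
                    f"exposure alleles {ea}/{oa} (on either strand)"
                )

        palindromic = _is_palindromic(ea, oa)
        if palindromic:
            if palindromic_policy == "drop":
                n_dropped_palindromic += 1
                logger.info("harmonize: %s is palindromic (%s/%s); dropped", exp.rsid, ea, oa)
                continue
            if palindromic_policy == "flag":
                logger.warning("harmonize: %s is palindromic (%s/%s); retained and flagged", exp.rsid, ea, oa)

        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                effect_allele=ea,
                other_allele=oa,
                beta_x=exp.beta,
                se_x=exp.se,
                beta_y=-out.beta if flipped else out.beta,
                se_y=out.se,
                eaf=exp.eaf,
                flipped=flipped,
                palindromic=palindromic,
            )
        )

    if not instruments:
        raise HarmonizationError(
            f"no instruments after harmonization ({n_missing} rsids missing from outcome, "
            f"{n_dropped_palindromic} palindromic dropped)"
        )
    if n_missing or n_dropped_palindromic:
        logger.info(
            "harmonize: retained %d instruments (%d missing from outcome, %d palindromic dropped)",
            len(instruments), n_missing, n_dropped_palindromic,
        )
    return InstrumentSet(instruments, sd_scale=sd_scale)


def rescale_per_sd(estimate, sd_scale: float):
    """Rescale an estimate from per-log-unit to per-SD of exposure.

    Multiplies the point estimate, SE, and CI bounds by ``sd_scale`` and
    leaves the p-value (hence every z-statistic) unchanged.  Works on any
    dataclass record carrying ``beta``, ``se``, ``ci_low``, ``ci_high``.
    """
    if not sd_scale > 0:
        raise ValueError(f"sd_scale must be positive, got {sd_scale}")
    return replace(
        estimate,
        beta=estimate.beta * sd_scale,
        se=estimate.se * sd_scale,
        ci_low=estimate.ci_low * sd_scale,
        ci_high=estimate.ci_high * sd_scale,
    )


def write_instruments(instrument_set: InstrumentSet, path) -> None:
    """Write a harmonized instrument table as tab-delimited text."""
    instrument_set.to_frame().to_csv(path, sep="\t", index=False)


def read_instruments(path, sd_scale: float = 0.65) -> InstrumentSet:
    """Read a harmonized instrument table written by :func:`write_instruments`."""
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "effect_allele", "other_allele", "beta_x", "se_x", "beta_y", "se_y"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    instruments = [
        HarmonizedInstrument(
            rsid=str(row.rsid),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            beta_x=float(row.beta_x),
            se_x=float(row.se_x),
            beta_y=float(row.beta_y),
            se_y=float(row.se_y),
            eaf=None if not hasattr(row, "eaf") or pd.isna(row.eaf) else float(row.eaf),
            flipped=bool(getattr(row, "flipped", False)),
            palindromic=bool(getattr(row, "palindromic", False)),
        )
        for row in df.itertuples(index=False)
    ]
    return InstrumentSet(instruments, sd_scale=sd_scale)
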