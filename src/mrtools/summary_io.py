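"""Reading, validating and writing GWAS summary-statistic tables.

A summary table is a delimited text file with one row per SNP.  Column
names differ between sources, so every reader takes a ``column_map`` from
semantic field names (``snp_id``, ``effect_allele``, ``other_allele``,
``beta``, ``se``, ``pvalue``, and optionally ``eaf``, ``chrom``, ``pos``)
to the column names actually present in the file.  Two named presets
cover the most common dialects.

Binary-trait sources frequently report odds ratios; when the associated
:class:`TraitMeta` declares ``effect_scale="odds_ratio"`` the effect
column is log-transformed on read and the standard-error column is taken
to be already on the log scale (the convention of GWAS downloads that
report OR alongside the SE of the log-OR).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "GwasRecord",
    "TraitMeta",
    "COLUMN_PRESETS",
    "read_gwas_table",
    "write_gwas_table",
    "write_mr_report",
    "write_mr_report_json",
]

_VALID_ALLELES = frozenset("ACGT")

#: Named column-map presets for common summary-statistic dialects.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "twosamplemr": {
        "snp_id": "SNP",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "beta",
        "se": "se",
        "pvalue": "pval",
        "eaf": "eaf",
    },
    "gwas_catalog": {
        "snp_id": "variant_id",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "beta": "beta",
        "se": "standard_error",
        "pvalue": "p_value",
        "eaf": "effect_allele_frequency",
        "chrom": "chromosome",
        "pos": "base_pair_location",
    },
}

_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
_OPTIONAL_FIELDS = ("eaf", "chrom", "pos")


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait, on the additive beta scale.

    ``beta`` is the per-allele effect of ``effect_allele``: log-OR for
    binary traits, SD units for continuous traits.  ``pos`` is 1-based.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self):
        if self.effect_allele not in _VALID_ALLELES:
            raise ValidationError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValidationError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.snp_id}: pvalue must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in (0, 1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True when the allele pair is strand-ambiguous (A/T or C/G)."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(frozen=True)
class TraitMeta:
    """How a trait's effects are reported."""

    trait_name: str
    trait_type: str = "continuous"  # continuous | binary
    effect_scale: str = "beta"  # beta | odds_ratio
    n_samples: int | None = None

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.effect_scale not in ("beta", "odds_ratio"):
            raise ConfigurationError(f"unknown effect_scale {self.effect_scale!r}")
        if self.effect_scale == "odds_ratio" and self.trait_type != "binary":
            raise ConfigurationError(
                f"{self.trait_name}: effect_scale='odds_ratio' requires trait_type='binary'"
            )


def resolve_column_map(column_map: str | Mapping[str, str] | None) -> dict[str, str]:
    """Expand a preset name into a concrete column map (identity-safe)."""
    if column_map is None:
        return dict(COLUMN_PRESETS["twosamplemr"])
    if isinstance(column_map, str):
        try:
            return dict(COLUMN_PRESETS[column_map])
        except KeyError:
            raise ConfigurationError(
                f"unknown column preset {column_map!r}; available: {sorted(COLUMN_PRESETS)}"
            ) from None
    return dict(column_map)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_gwas_table(
    path: str | Path,
    column_map: str | Mapping[str, str] | None = None,
    trait_meta: TraitMeta | None = None,
    delimiter: str | None = None,
) -> list[GwasRecord]:
    """Read one summary-statistic table into validated :class:`GwasRecord` rows.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    column_map:
        Mapping from semantic field to column name, or a preset name
        (``"twosamplemr"``, ``"gwas_catalog"``).  Optional fields whose
        mapped column is absent from the file are treated as missing.
    trait_meta:
        Trait description; when ``effect_scale="odds_ratio"`` the effect
        column is natural-log-transformed and the SE column is taken as
        already on the log scale.
    delimiter:
        Explicit delimiter; auto-detected from the header when ``None``.

    Raises
    ------
    ConfigurationError
        If a required mapped column is missing from the header.
    ValidationError
        If any row violates a record invariant; the error lists the
        offending zero-based data-row indices.
    """
    path = Path(path)
    cmap = resolve_column_map(column_map)
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, engine="python")

    for semantic in _REQUIRED_FIELDS:
        col = cmap.get(semantic)
        if col is None:
            raise ConfigurationError(f"column_map lacks required field {semantic!r}")
        if col not in df.columns:
            raise ConfigurationError(
                f"{path.name}: required column {col!r} (field {semantic!r}) not in header "
                f"{list(df.columns)}"
            )

    log_scale = trait_meta is not None and trait_meta.effect_scale == "odds_ratio"

    records: list[GwasRecord] = []
    bad_rows: list[int] = []
    messages: list[str] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            beta = float(row[cmap["beta"]])
            if log_scale:
                if beta <= 0:
                    raise ValidationError(f"odds ratio must be > 0, got {beta}")
                beta = math.log(beta)
            eaf = None
            if "eaf" in cmap and cmap["eaf"] in df.columns:
                raw = row[cmap["eaf"]]
                eaf = None if pd.isna(raw) else float(raw)
            chrom = None
            if "chrom" in cmap and cmap["chrom"] in df.columns:
                raw = row[cmap["chrom"]]
                if pd.isna(raw):
                    chrom = None
                elif isinstance(raw, float) and raw.is_integer():
                    chrom = str(int(raw))  # mixed NaN column upcast to float
                else:
                    chrom = str(raw)
            pos = None
            if "pos" in cmap and cmap["pos"] in df.columns:
                raw = row[cmap["pos"]]
                pos = None if pd.isna(raw) else int(raw)
            records.append(
                GwasRecord(
                    snp_id=str(row[cmap["snp_id"]]),
                    effect_allele=str(row[cmap["effect_allele"]]).upper(),
                    other_allele=str(row[cmap["other_allele"]]).upper(),
                    beta=beta,
                    se=float(row[cmap["se"]]),
                    pvalue=float(row[cmap["pvalue"]]),
                    eaf=eaf,
                    chrom=chrom,
                    pos=pos,
                )
            )
        except (ValidationError, ValueError) as exc:
            bad_rows.append(i)
            messages.append(f"row {i}: {exc}")
    if bad_rows:
        raise ValidationError(
            f"{path.name}: {len(bad_rows)} invalid rows -- " + "; ".join(messages), rows=bad_rows
        )
    return records


def write_gwas_table(records: Iterable[GwasRecord], path: str | Path) -> None:
    """Write records in the ``twosamplemr`` preset layout (TSV)."""
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": _fmt(r.beta),
                "se": _fmt(r.se),
                "pval": _fmt(r.pvalue),
                "eaf": "" if r.eaf is None else _fmt(r.eaf),
                "chrom": "" if r.chrom is None else r.chrom,
                "pos": "" if r.pos is None else r.pos,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x: float) -> str:
    # 17 significant digits round-trips IEEE doubles exactly
    return format(float(x), ".17g")


REPORT_COLUMNS = (
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "OR",
    "ci_low",
    "ci_high",
    "pvalue",
)


def write_mr_report(results: Sequence, path: str | Path) -> None:
    """Serialize causal estimates as a tab-delimited report.

    ``results`` is a sequence of objects exposing the attributes of
    :class:`mrtools.estimators.MrEstimate` plus ``exposure``/``outcome``
    labels (see :func:`mrtools.estimators.labelled`).  Floats are written
    with 17 significant digits so a read-back round-trips exactly.
    """
    if not results:
        raise ValueError("write_mr_report requires a non-empty result list")
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "method": r.method,
                "n_snp": r.n_snp,
                "beta": _fmt(r.beta),
                "se": _fmt(r.se),
                "OR": _fmt(r.odds_ratio),
                "ci_low": _fmt(r.ci_low),
                "ci_high": _fmt(r.ci_high),
                "pvalue": _fmt(r.pvalue),
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mr_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_mr_report`."""
    return pd.read_csv(path, sep="\t")


def write_mr_report_json(results: Sequence, path: str | Path) -> None:
    """Full-precision JSON companion of :func:`write_mr_report`."""
    payload = [
        {
            "exposure": r.exposure,
            "outcome": r.outcome,
            "method": r.method,
            "n_snp": int(r.n_snp),
            "beta": float(r.beta),
            "se": float(r.se),
            "OR": float(r.odds_ratio),
            "ci_low": float(r.ci_low),
            "ci_high": float(r.ci_high),
            "pvalue": float(r.pvalue),
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
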