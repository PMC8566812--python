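"""Instrument selection, LD clumping, proxy substitution and allele harmonization.

The end product is a :class:`HarmonizedSet`: per-SNP exposure effects
``X`` with standard errors ``se_X`` and outcome effects ``Y`` with
standard errors ``se_Y``, all expressed for the same effect allele, plus
an audit trail of every SNP that was flipped, proxied or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyHarmonizedSetError, ValidationError
from .summary_io import GwasRecord

__all__ = [
    "HarmonizedSet",
    "HarmonizedSnp",
    "Dropped",
    "LdInfo",
    "select_instruments",
    "clump",
    "substitute_proxies",
    "harmonize_pair",
    "build_harmonized_set",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# per-SNP harmonization flags
FLAG_UNCHANGED = "unchanged"
FLAG_FLIPPED = "allele_flipped"
FLAG_PALINDROMIC = "palindromic_kept"
FLAG_PROXY = "proxy_substituted"


@dataclass(frozen=True)
class HarmonizedSnp:
    """One exposure/outcome pair aligned to a common effect allele."""

    snp_id: str
    X: float
    se_X: float
    Y: float
    se_Y: float
    flag: str
    outcome_eaf: float | None = None


@dataclass(frozen=True)
class Dropped:
    """Drop signal: why a SNP left the analysis."""

    snp_id: str
    reason: str


@dataclass(frozen=True)
class ProxyChoice:
    """Outcome-side proxy chosen for an instrument absent from the outcome data.

    ``phase`` states how the proxy's effect allele maps onto the
    instrument's: ``"same"`` (aligned), ``"swap"`` (anti-aligned) or
    ``None`` (unstated in the proxy table; alignment falls back to
    frequency matching and is logged).
    """

    record: GwasRecord
    r2: float
    phase: str | None = None


@dataclass
class HarmonizedSet:
    """Analysis-ready aligned summary statistics for one exposure → outcome pair."""

    exposure_name: str
    outcome_name: str
    snp_ids: list[str]
    X: np.ndarray
    se_X: np.ndarray
    Y: np.ndarray
    se_Y: np.ndarray
    flags: list[str] = field(default_factory=list)
    audit: list[Dropped] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.se_X = np.asarray(self.se_X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.se_Y = np.asarray(self.se_Y, dtype=float)
        k = len(self.snp_ids)
        if not (len(self.X) == len(self.se_X) == len(self.Y) == len(self.se_Y) == k):
            raise ValidationError("HarmonizedSet vectors must share one length")
        if k == 0:
            raise EmptyHarmonizedSetError(
                f"empty harmonized set for {self.exposure_name} -> {self.outcome_name}"
            )
        if len(set(self.snp_ids)) != k:
            raise ValidationError("snp_ids must be unique")
        if not (np.all(self.se_X > 0) and np.all(self.se_Y > 0)):
            raise ValidationError("standard errors must be strictly positive")
        if not self.flags:
            self.flags = [FLAG_UNCHANGED] * k

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int]) -> "HarmonizedSet":
        """New set restricted to positional indices ``keep`` (audit not carried)."""
        keep = list(keep)
        return HarmonizedSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            snp_ids=[self.snp_ids[i] for i in keep],
            X=self.X[keep],
            se_X=self.se_X[keep],
            Y=self.Y[keep],
            se_Y=self.se_Y[keep],
            flags=[self.flags[i] for i in keep],
        )

    def sorted_by_snp(self) -> "HarmonizedSet":
        """Canonical order: ascending ``snp_id``."""
        order = sorted(range(self.n_snp), key=lambda i: self.snp_ids[i])
        return self.subset(order)


class LdInfo:
    """Pairwise LD (r²) plus per-SNP positions, consumed from user tables.

    ``pairs`` maps an unordered SNP-id pair to r²; unknown pairs are
    treated according to the clumping mode.  Positions come from the
    records themselves when present, or from ``positions``.
    """

    def __init__(
        self,
        pairs: Mapping[tuple[str, str], float] | None = None,
        positions: Mapping[str, tuple[str, int]] | None = None,
    ):
        self._pairs: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            if not (0.0 <= r2 <= 1.0):
                raise ValidationError(f"r2 out of [0,1] for pair ({a}, {b}): {r2}")
            self._pairs[frozenset((a, b))] = float(r2)
        self.positions = dict(positions or {})

    def r2(self, a: str, b: str) -> float | None:
        """r² between two SNPs; 1.0 on the diagonal; None when unknown."""
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)))

    @classmethod
    def from_pair_table(cls, path: str | Path, positions=None) -> "LdInfo":
        """Load a TSV pair list with columns ``snp_a``, ``snp_b``, ``r2``."""
        df = pd.read_csv(path, sep="\t")
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise ConfigurationError(f"LD pair table lacks column {col!r}")
        pairs = {
            (str(r.snp_a), str(r.snp_b)): float(r.r2) for r in df.itertuples(index=False)
        }
        return cls(pairs, positions)

    @classmethod
    def from_matrix(cls, path: str | Path, positions=None) -> "LdInfo":
        """Load a square r² matrix (TSV, SNP ids as index and header)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        pairs = {}
        ids = list(df.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                pairs[(str(a), str(b))] = float(df.loc[a, b])
        return cls(pairs, positions)


def select_instruments(
    records: Sequence[GwasRecord], p_threshold: float = 5e-8
) -> list[GwasRecord]:
    """Keep records with ``pvalue < p_threshold`` (strict), order preserved."""
    if not (0 < p_threshold < 1):
        raise ConfigurationError(f"p_threshold must be in (0,1), got {p_threshold}")
    return [r for r in records if r.pvalue < p_threshold]


def clump(
    records: Sequence[GwasRecord],
    ld: LdInfo,
    r2_max: float = 0.01,
    window_bp: int = 1_000_000,
    strict: bool = True,
) -> list[GwasRecord]:
    """Greedy LD clumping.

    Records are visited by ascending p-value (ties broken by chrom, pos,
    snp_id); a record is accepted iff no already-accepted record on the
    same chromosome lies within ``window_bp`` of it AND has r² strictly
    greater than ``r2_max`` with it.  In strict mode an unknown r² for an
    in-window pair is an error; in lenient mode it is treated as r² = 1
    (conservative removal).
    """
    def position(r: GwasRecord) -> tuple[str, int]:
        if r.chrom is not None and r.pos is not None:
            return r.chrom, r.pos
        if r.snp_id in ld.positions:
            return ld.positions[r.snp_id]
        raise ConfigurationError(f"no position available for {r.snp_id}; clumping needs one")

    order = sorted(
        records, key=lambda r: (r.pvalue, position(r)[0], position(r)[1], r.snp_id)
    )
    accepted: list[GwasRecord] = []
    for cand in order:
        c_chrom, c_pos = position(cand)
        ok = True
        for kept in accepted:
            k_chrom, k_pos = position(kept)
            if k_chrom != c_chrom or abs(k_pos - c_pos) > window_bp:
                continue
            r2 = ld.r2(cand.snp_id, kept.snp_id)
            if r2 is None:
                if strict:
                    raise ConfigurationError(
                        f"missing r2 for in-window pair ({cand.snp_id}, {kept.snp_id})"
                    )
                r2 = 1.0
            if r2 > r2_max:
                ok = False
                break
        if ok:
            accepted.append(cand)
    # restore input order among survivors
    kept_ids = {r.snp_id for r in accepted}
    return [r for r in records if r.snp_id in kept_ids]


def substitute_proxies(
    missing: Sequence[str],
    proxy_table: Mapping[str, Sequence[tuple]],
    outcome_records: Mapping[str, GwasRecord],
    r2_min: float = 0.8,
) -> tuple[dict[str, ProxyChoice], list[Dropped]]:
    """Find outcome-side proxies for instruments absent from the outcome data.

    ``proxy_table`` maps an instrument id to candidate tuples
    ``(proxy_id, r2)`` or ``(proxy_id, r2, phase)`` with phase in
    ``{"same", "swap"}``.  For each missing SNP the available proxy with
    the highest r² ≥ ``r2_min`` that is present in ``outcome_records`` is
    chosen; ties are broken by lexicographic proxy id.  Returns the
    substitution mapping and the list of SNPs dropped for lack of an
    eligible proxy.
    """
    chosen: dict[str, ProxyChoice] = {}
    dropped: list[Dropped] = []
    for snp in missing:
        candidates = []
        for entry in proxy_table.get(snp, []):
            pid, r2 = entry[0], float(entry[1])
            phase = entry[2] if len(entry) > 2 else None
            if r2 >= r2_min and pid in outcome_records:
                candidates.append((pid, r2, phase))
        if not candidates:
            dropped.append(Dropped(snp, "no_proxy"))
            continue
        # max r2, ties by lexicographic proxy id
        pid, r2, phase = min(candidates, key=lambda c: (-c[1], c[0]))
        chosen[snp] = ProxyChoice(outcome_records[pid], r2, phase)
    return chosen, dropped


def _complement_record_alleles(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def harmonize_pair(
    exp: GwasRecord,
    out: GwasRecord,
    palindromic_mode: str = "keep",
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSnp | Dropped:
    """Align one outcome record to the exposure record's effect allele.

    Non-palindromic pairs: identical allele coding passes through;
    swapped coding negates the outcome beta (and reflects its frequency);
    strand-complement coding is complemented first, then the same rules
    apply.  Palindromic pairs (A/T, C/G) are handled per
    ``palindromic_mode``:

    - ``keep``: compare allele strings literally (forward-strand
      assumption) and retain, flagged ``palindromic_kept``;
    - ``drop``: always drop;
    - ``frequency``: retain only when both effect-allele frequencies are
      available, on the same side of 0.5, and outside the ambiguity
      window.
    """
    if palindromic_mode not in ("keep", "drop", "frequency"):
        raise ConfigurationError(f"unknown palindromic_mode {palindromic_mode!r}")

    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    palindromic = exp.is_palindromic

    if palindromic:
        if out.is_palindromic and {o_ea, o_oa} != {e_ea, e_oa}:
            return Dropped(exp.snp_id, "incompatible_alleles")
        if not out.is_palindromic:
            return Dropped(exp.snp_id, "incompatible_alleles")
        if palindromic_mode == "drop":
            return Dropped(exp.snp_id, "palindromic")
        if palindromic_mode == "frequency":
            if exp.eaf is None or out.eaf is None:
                return Dropped(exp.snp_id, "palindromic_no_frequency")
            lo, hi = ambiguity_window
            # literal comparison fixes which outcome frequency refers to the
            # exposure effect allele under the forward-strand assumption
            out_eaf = out.eaf if o_ea == e_ea else 1.0 - out.eaf
            if not (lo > exp.eaf or exp.eaf > hi) or not (lo > out_eaf or out_eaf > hi):
                return Dropped(exp.snp_id, "palindromic_ambiguous_frequency")
            if (exp.eaf < 0.5) != (out_eaf < 0.5):
                return Dropped(exp.snp_id, "palindromic_frequency_discordant")
        # keep / frequency-pass: literal forward-strand comparison
        if (o_ea, o_oa) == (e_ea, e_oa):
            return HarmonizedSnp(
                exp.snp_id, exp.beta, exp.se, out.beta, out.se, FLAG_PALINDROMIC, out.eaf
            )
        # swapped coding on the forward strand
        return HarmonizedSnp(
            exp.snp_id,
            exp.beta,
            exp.se,
            -out.beta,
            out.se,
            FLAG_PALINDROMIC,
            None if out.eaf is None else 1.0 - out.eaf,
        )

    # non-palindromic: try literal, then strand-complemented coding
    for attempt, (ea, oa) in enumerate(
        ((o_ea, o_oa), _complement_record_alleles(o_ea, o_oa))
    ):
        if (ea, oa) == (e_ea, e_oa):
            return HarmonizedSnp(
                exp.snp_id, exp.beta, exp.se, out.beta, out.se, FLAG_UNCHANGED, out.eaf
            )
        if (oa, ea) == (e_ea, e_oa):
            return HarmonizedSnp(
                exp.snp_id,
                exp.beta,
                exp.se,
                -out.beta,
                out.se,
                FLAG_FLIPPED,
                None if out.eaf is None else 1.0 - out.eaf,
            )
    return Dropped(exp.snp_id, "incompatible_alleles")


def build_harmonized_set(
    exposure: Sequence[GwasRecord],
    outcome: Mapping[str, GwasRecord] | Iterable[GwasRecord],
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    proxy_table: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    proxy_r2_min: float = 0.8,
    palindromic_mode: str = "keep",
) -> HarmonizedSet:
    """Merge selected exposure instruments with the outcome lookup.

    Applies proxy substitution for instruments absent from the outcome
    data, then per-SNP allele harmonization.  Every drop is recorded in
    the returned set's ``audit``; an empty result raises
    :class:`EmptyHarmonizedSetError` naming the analysis.
    """
    if not isinstance(outcome, Mapping):
        outcome = {r.snp_id: r for r in outcome}

    missing = [r.snp_id for r in exposure if r.snp_id not in outcome]
    proxies, proxy_dropped = substitute_proxies(
        missing, proxy_table or {}, outcome, r2_min=proxy_r2_min
    )

    snp_ids: list[str] = []
    X, se_X, Y, se_Y = [], [], [], []
    flags: list[str] = []
    audit: list[Dropped] = list(proxy_dropped)
    notes: list[str] = []

    for exp in exposure:
        if exp.snp_id in outcome:
            result = harmonize_pair(
                exp, outcome[exp.snp_id], palindromic_mode=palindromic_mode
            )
            if isinstance(result, Dropped):
                audit.append(result)
                continue
            flag = result.flag
        elif exp.snp_id in proxies:
            result = _harmonize_via_proxy(exp, proxies[exp.snp_id], notes)
            if isinstance(result, Dropped):
                audit.append(result)
                continue
            flag = FLAG_PROXY
        else:
            continue  # already audited by substitute_proxies
        snp_ids.append(result.snp_id)
        X.append(result.X)
        se_X.append(result.se_X)
        Y.append(result.Y)
        se_Y.append(result.se_Y)
        flags.append(flag)

    if not snp_ids:
        raise EmptyHarmonizedSetError(
            f"no SNP survived harmonization for {exposure_name} -> {outcome_name} "
            f"({len(audit)} drops: {[d.reason for d in audit]})"
        )
    hset = HarmonizedSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        snp_ids=snp_ids,
        X=np.array(X),
        se_X=np.array(se_X),
        Y=np.array(Y),
        se_Y=np.array(se_Y),
        flags=flags,
        audit=audit,
        notes=notes,
    )
    return hset


def _harmonize_via_proxy(
    exp: GwasRecord, choice: ProxyChoice, notes: list[str]
) -> HarmonizedSnp | Dropped:
    """Align a proxy outcome record to the instrument.

    With stated phase the mapping is explicit; without it alignment falls
    back to effect-allele-frequency matching (same side of 0.5 keeps the
    sign) and logs the fallback; with neither phase nor frequencies the
    record is kept as-is and logged.
    """
    out = choice.record
    if choice.phase == "same":
        sign = 1.0
    elif choice.phase == "swap":
        sign = -1.0
    elif exp.eaf is not None and out.eaf is not None:
        sign = 1.0 if (exp.eaf < 0.5) == (out.eaf < 0.5) else -1.0
        notes.append(
            f"{exp.snp_id}: proxy {out.snp_id} aligned by frequency matching "
            f"(sign {'+' if sign > 0 else '-'})"
        )
    else:
        sign = 1.0
        notes.append(
            f"{exp.snp_id}: proxy {out.snp_id} has no phase and no frequencies; kept as-is"
        )
    return HarmonizedSnp(
        exp.snp_id, exp.beta, exp.se, sign * out.beta, out.se, FLAG_PROXY, out.eaf
    )
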