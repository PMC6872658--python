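"""Relative-abundance (RA) quantification of single histone PTMs.

The RA of modification *i* on a peptide pool is

    RA(i) = sum(intensities of peptidoforms carrying i)
          / sum(intensities of all peptidoforms of the pool)

where the *pool* is every peptidoform sharing one peptide backbone (span)
within one variant group.  RA is a ratio statistic: it is invariant to
rescaling a sample's column and, per residue, the modified-state RAs plus the
unmodified share sum to one.

Ambiguity is handled by *merging* at the intensity level, never by averaging
RAs: variant groups that cannot be told apart (H3.1/H3.2 vs H3.3 outside a
distinguishing position) and neighbouring residues whose fragment ions rarely
resolve them (K36 vs K37) are re-aggregated from the supporting peptidoform
rows and recomputed.

Row descriptor grammar (the wide-table index):

    FAMILY VARIANTGROUP SPAN MODLIST
    e.g.  "H3 H31/H32 27-40 K27me3+K36me2"
          "H3 H33 27-40 unmod"
          "H3 H31/H32 c28-40 unmod"      (clipped N-terminus: span prefixed c)
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HPTMKey",
    "AbundanceMatrix",
    "RAMatrix",
    "parse_descriptor",
    "format_descriptor",
    "compute_ra",
    "ra_matrix",
    "merge_keys",
    "quantify_clipping",
    "co_detection_groups",
    "enumerate_keys",
    "unmodified_share",
    "median_ratio_normalize",
]

logger = logging.getLogger(__name__)

_RESIDUE_RE = re.compile(r"^([A-Z])(\d+(?:/\d+)*)$")
_MOD_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([a-z][a-z0-9]*)$")
_SAMPLE_RE = re.compile(r"^(?P<passage>[^_]+)_R(?P<replicate>\d+)$")


@dataclass(frozen=True, order=True)
class HPTMKey:
    """(variant group, residue, modification) with optional clipped flag.

    ``residue`` is a single site ("K27") or a "/"-merged pair ("K36/37").
    Clipping keys use ``mod=""`` and ``clipped=True``.
    """

    variant_group: str
    residue: str
    mod: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if not _RESIDUE_RE.match(self.residue):
            raise ValueError(f"bad residue label {self.residue!r}")
        if self.clipped and self.mod:
            raise ValueError("clipping keys carry no modification name")
        if not self.clipped and not self.mod:
            raise ValueError("non-clipping keys need a modification name")

    @property
    def residue_letter(self) -> str:
        return _RESIDUE_RE.match(self.residue).group(1)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(int(p) for p in _RESIDUE_RE.match(self.residue).group(2).split("/"))

    @property
    def label(self) -> str:
        if self.clipped:
            return f"{self.variant_group} c{self.residue}"
        return f"{self.variant_group} {self.residue}{self.mod}"


def parse_descriptor(descriptor: str) -> dict:
    """Parse a ``FAMILY VARIANTGROUP SPAN MODLIST`` row descriptor."""
    parts = descriptor.split()
    if len(parts) != 4:
        raise ValueError(f"descriptor {descriptor!r}: expected 4 space-separated fields")
    family, vg, span, modlist = parts
    clipped = span.startswith("c")
    if clipped:
        span = span[1:]
    m = re.match(r"^(\d+)-(\d+)$", span)
    if not m:
        raise ValueError(f"descriptor {descriptor!r}: bad span {span!r}")
    start, end = int(m.group(1)), int(m.group(2))
    if end < start:
        raise ValueError(f"descriptor {descriptor!r}: span end before start")
    mods: list[tuple[str, int, str]] = []
    if modlist != "unmod":
        for token in modlist.split("+"):
            tm = _MOD_TOKEN_RE.match(token)
            if not tm:
                raise ValueError(f"descriptor {descriptor!r}: bad mod token {token!r}")
            letter, pos, name = tm.group(1), int(tm.group(2)), tm.group(3)
            if not start <= pos <= end:
                raise ValueError(
                    f"descriptor {descriptor!r}: mod position {pos} outside span"
                )
            mods.append((letter, pos, name))
    return {
        "family": family,
        "variant_group": vg,
        "start": start,
        "end": end,
        "clipped": clipped,
        "mods": tuple(sorted(mods, key=lambda t: (t[1], t[2]))),
    }


def format_descriptor(
    family: str,
    variant_group: str,
    start: int,
    end: int,
    mods: Sequence[tuple[str, int, str]] = (),
    clipped: bool = False,
) -> str:
    span = f"{'c' if clipped else ''}{start}-{end}"
    if mods:
        modlist = "+".join(
            f"{letter}{pos}{name}"
            for letter, pos, name in sorted(mods, key=lambda t: (t[1], t[2]))
        )
    else:
        modlist = "unmod"
    return f"{family} {variant_group} {span} {modlist}"


@dataclass
class AbundanceMatrix:
    """Peptidoform x sample normalized intensities plus parsed row metadata."""

    values: pd.DataFrame
    meta: pd.DataFrame
    normalization_tag: str = "as-imported"

    @classmethod
    def from_wide(
        cls, table: pd.DataFrame, normalization_tag: str = "as-imported"
    ) -> "AbundanceMatrix":
        """Build from a wide table (index = descriptors, columns = samples)."""
        dup = table.index[table.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate peptidoform rows: {dup}")
        for col in table.columns:
            if not _SAMPLE_RE.match(str(col)):
                raise ValueError(
                    f"sample name {col!r} does not match 'P<passage>_R<replicate>'"
                )
        values = table.astype(float)
        if (values < 0).any().any():
            raise ValueError("negative abundances are not allowed")
        meta = pd.DataFrame(
            [parse_descriptor(str(d)) for d in table.index], index=table.index
        )
        return cls(values=values, meta=meta, normalization_tag=normalization_tag)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def sample_passages(self) -> pd.Series:
        """Passage label per sample column, parsed from ``P<passage>_R<rep>``."""
        return pd.Series(
            {c: _SAMPLE_RE.match(str(c)).group("passage") for c in self.values.columns}
        )


def _pool_rows(matrix: AbundanceMatrix, variant_group: str, positions: Sequence[int]):
    meta = matrix.meta
    lo, hi = min(positions), max(positions)
    mask = (
        (~meta["clipped"])
        & (meta["variant_group"] == variant_group)
        & (meta["start"] <= lo)
        & (meta["end"] >= hi)
    )
    return meta.index[mask]


def _carrier_rows(matrix: AbundanceMatrix, key: HPTMKey, pool_index) -> pd.Index:
    pos_set = set(key.positions)
    carriers = [
        idx
        for idx in pool_index
        if any(
            p in pos_set and name == key.mod
            for _, p, name in matrix.meta.at[idx, "mods"]
        )
    ]
    return pd.Index(carriers)


def _ratio(num: pd.Series, den: pd.Series, what: str) -> pd.Series:
    zero = (den == 0) | den.isna()
    if zero.any():
        logger.warning(
            "%s: pool total missing or zero in %d sample(s); RA set to missing",
            what,
            int(zero.sum()),
        )
    out = num / den.where(~zero)
    return out


def compute_ra(matrix: AbundanceMatrix, key: HPTMKey) -> pd.Series:
    """Per-sample RA of one hPTM key.

    The denominator is the key's peptide pool: every non-clipped peptidoform
    of the same variant group whose span covers the residue.  Samples with a
    zero or missing pool total yield a missing value (never 0/0 -> 0).
    """
    if key.clipped:
        raise ValueError("use quantify_clipping for clipping keys")
    pool = _pool_rows(matrix, key.variant_group, key.positions)
    if len(pool) == 0:
        raise ValueError(f"no peptide pool covers {key.label}")
    carriers = _carrier_rows(matrix, key, pool)
    den = matrix.values.loc[pool].sum(axis=0, skipna=False)
    num = matrix.values.loc[carriers].sum(axis=0, skipna=False)
    return _ratio(num, den, key.label)


@dataclass
class RAMatrix:
    """hPTM key x sample RA values, retaining supporting-row provenance.

    ``carrier_rows`` / ``pool_rows`` map each key label to the row sets it was
    computed from, which makes intensity-level merging and co-detection
    analysis exact rather than approximate.
    """

    values: pd.DataFrame
    keys: dict[str, HPTMKey]
    carrier_rows: dict[str, frozenset]
    pool_rows: dict[str, frozenset]
    source: AbundanceMatrix

    def key_list(self) -> list[HPTMKey]:
        return [self.keys[label] for label in self.values.index]


def ra_matrix(matrix: AbundanceMatrix, keys: Iterable[HPTMKey]) -> RAMatrix:
    """Compute RA for every key, recording supporting rows per key."""
    rows, keymap, carrier_map, pool_map = [], {}, {}, {}
    for key in keys:
        if key.clipped:
            pool = matrix.meta.index[
                (~matrix.meta["clipped"])
                & (matrix.meta["variant_group"] == key.variant_group)
                & (matrix.meta["start"] <= key.positions[0])
                & (matrix.meta["end"] >= key.positions[0])
            ]
            carriers = matrix.meta.index[
                matrix.meta["clipped"]
                & (matrix.meta["variant_group"] == key.variant_group)
                & (matrix.meta["start"] == key.positions[0] + 1)
            ]
            den = matrix.values.loc[pool.union(carriers)].sum(axis=0, skipna=False)
            num = matrix.values.loc[carriers].sum(axis=0, skipna=False)
            ra = _ratio(num, den, key.label)
            pool = pool.union(carriers)
        else:
            pool = _pool_rows(matrix, key.variant_group, key.positions)
            if len(pool) == 0:
                raise ValueError(f"no peptide pool covers {key.label}")
            carriers = _carrier_rows(matrix, key, pool)
            den = matrix.values.loc[pool].sum(axis=0, skipna=False)
            num = matrix.values.loc[carriers].sum(axis=0, skipna=False)
            ra = _ratio(num, den, key.label)
        rows.append(ra.rename(key.label))
        keymap[key.label] = key
        carrier_map[key.label] = frozenset(carriers)
        pool_map[key.label] = frozenset(pool)
    values = pd.DataFrame(rows) if rows else pd.DataFrame(columns=matrix.samples)
    return RAMatrix(
        values=values,
        keys=keymap,
        carrier_rows=carrier_map,
        pool_rows=pool_map,
        source=matrix,
    )


def merge_keys(
    ra: RAMatrix, rules: Sequence[tuple[HPTMKey, Sequence[HPTMKey | str]]]
) -> RAMatrix:
    """Merge keys by re-aggregating intensities at the peptidoform level.

    Each rule is ``(merged_key, members)``.  The merged RA is the union of
    the members' carrier rows over the union of their pools — i.e. an
    intensity-weighted combination when pools are disjoint (variant merging)
    and an exact de-duplicated recount when pools are shared (residue
    merging).  A key referenced by two rules is an error; merging a key with
    itself is the identity.
    """
    member_labels = lambda ms: [m if isinstance(m, str) else m.label for m in ms]
    seen: set[str] = set()
    for _, members in rules:
        for label in member_labels(members):
            if label not in ra.keys:
                raise ValueError(f"merge rule references unknown key {label!r}")
            if label in seen:
                raise ValueError(f"key {label!r} appears in more than one merge group")
            seen.add(label)

    values = {}
    keymap: dict[str, HPTMKey] = {}
    carrier_map: dict[str, frozenset] = {}
    pool_map: dict[str, frozenset] = {}
    for label in ra.values.index:
        if label not in seen:
            keymap[label] = ra.keys[label]
            carrier_map[label] = ra.carrier_rows[label]
            pool_map[label] = ra.pool_rows[label]
            values[label] = ra.values.loc[label]
    for merged_key, members in rules:
        labels = member_labels(members)
        carriers = frozenset().union(*(ra.carrier_rows[l] for l in labels))
        pool = frozenset().union(*(ra.pool_rows[l] for l in labels))
        num = ra.source.values.loc[sorted(carriers)].sum(axis=0, skipna=False)
        den = ra.source.values.loc[sorted(pool)].sum(axis=0, skipna=False)
        values[merged_key.label] = _ratio(num, den, merged_key.label)
        keymap[merged_key.label] = merged_key
        carrier_map[merged_key.label] = carriers
        pool_map[merged_key.label] = pool
    out = pd.DataFrame(values).T
    out = out.loc[sorted(keymap)]
    return RAMatrix(
        values=out,
        keys=keymap,
        carrier_rows=carrier_map,
        pool_rows=pool_map,
        source=ra.source,
    )


def quantify_clipping(
    matrix: AbundanceMatrix, clip_site: int, variant_group: str | None = None
) -> pd.Series:
    """Per-sample RA of the clipping event at ``clip_site``.

    RA = clipped-form intensities / (clipped + intact pool covering the
    site).  Absent clipped rows give 0; an absent intact pool gives missing
    values with a warning.
    """
    meta = matrix.meta
    vg_mask = (
        meta["variant_group"] == variant_group
        if variant_group is not None
        else pd.Series(True, index=meta.index)
    )
    clipped = meta.index[meta["clipped"] & (meta["start"] == clip_site + 1) & vg_mask]
    intact = meta.index[
        (~meta["clipped"]) & (meta["start"] <= clip_site) & (meta["end"] >= clip_site) & vg_mask
    ]
    if len(intact) == 0:
        logger.warning("no intact pool covers clip site %d; RA missing", clip_site)
        return pd.Series(np.nan, index=matrix.values.columns)
    clip_sum = matrix.values.loc[clipped].sum(axis=0, skipna=False)
    intact_sum = matrix.values.loc[intact].sum(axis=0, skipna=False)
    return _ratio(clip_sum, clip_sum + intact_sum, f"clipping@{clip_site}")


def enumerate_keys(matrix: AbundanceMatrix) -> list[HPTMKey]:
    """Every (variant group, residue, mod) key observed on any row."""
    keys = set()
    for idx in matrix.meta.index:
        row = matrix.meta.loc[idx]
        for letter, pos, name in row["mods"]:
            keys.add(
                HPTMKey(
                    variant_group=row["variant_group"],
                    residue=f"{letter}{pos}",
                    mod=name,
                )
            )
    return sorted(keys)


def co_detection_groups(
    matrix: AbundanceMatrix, keys: Iterable[HPTMKey] | None = None
) -> list[list[HPTMKey]]:
    """Partition keys by exact equality of their supporting (carrier) rows.

    Keys sharing one group are carried by exactly the same peptidoforms and
    therefore have identical RA in every sample (e.g. two mods only ever seen
    together on one backbone).
    """
    if keys is None:
        keys = enumerate_keys(matrix)
    ra = ra_matrix(matrix, keys)
    by_support: dict[tuple[frozenset, frozenset], list[HPTMKey]] = {}
    for label, key in ra.keys.items():
        sig = (ra.carrier_rows[label], ra.pool_rows[label])
        by_support.setdefault(sig, []).append(key)
    return [sorted(group) for group in by_support.values()]


def unmodified_share(
    matrix: AbundanceMatrix, variant_group: str, residue: str
) -> pd.Series:
    """Share of the pool unmodified at ``residue`` (per-residue remainder).

    Together with the RAs of the mutually exclusive modified states at the
    residue this sums to 1 per sample.
    """
    m = _RESIDUE_RE.match(residue)
    if not m:
        raise ValueError(f"bad residue label {residue!r}")
    positions = {int(p) for p in m.group(2).split("/")}
    pool = _pool_rows(matrix, variant_group, sorted(positions))
    if len(pool) == 0:
        raise ValueError(f"no peptide pool covers {variant_group} {residue}")
    unmod = [
        idx
        for idx in pool
        if not any(p in positions for _, p, _ in matrix.meta.at[idx, "mods"])
    ]
    den = matrix.values.loc[pool].sum(axis=0, skipna=False)
    num = matrix.values.loc[unmod].sum(axis=0, skipna=False)
    return _ratio(num, den, f"{variant_group} {residue} unmodified")


def median_ratio_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Optional median-of-ratios column normalization for raw tables.

    Size factor per sample = median of (value / geometric row mean) over rows
    positive in every sample; returns the scaled table and the factors.
    """
    complete = table.replace(0, np.nan).dropna()
    if complete.empty:
        raise ValueError("no row is positive in every sample; cannot normalize")
    log_geo = np.log(complete).mean(axis=1)
    factors = np.exp(np.log(complete).sub(log_geo, axis=0).median(axis=0))
    return table.div(factors, axis=1), factors
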