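"""Readers and writers for the fragment-map and count-table dialects.

Capture Hi-C callers in the CHiCAGO tradition describe the restriction
digest through two tab-delimited files: an *rmap* (chrom, start, end,
fragmentID) listing every fragment, and a *baitmap* (chrom, start, end,
fragmentID, name) listing the captured subset.  Per-replicate read counts
arrive in a *chinput*-like table (baitID, otherEndID, N, otherEndLen,
distSign).  This module is the only place files are touched; everything
downstream works on the validated in-memory containers defined here.

Coordinates are 1-based inclusive throughout, matching the dialects in the
wild; conversion to 0-based half-open happens only inside the BED-pair
writer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "FragmentMap",
    "InteractionTable",
    "read_fragment_map",
    "write_fragment_map",
    "read_interactions",
    "write_interactions",
    "read_scored_interactions",
    "write_scored_interactions",
]


class ParseError(ValueError):
    """Raised when an input file violates its dialect contract."""


@dataclass
class FragmentMap:
    """Ordered restriction fragments with bait designation.

    ``fragments`` holds one row per fragment (columns ``chrom``, ``start``,
    ``end``, ``id``), sorted by chromosome then start.  Within a chromosome
    fragments are non-overlapping and expected to be contiguous (a digest
    tiles the chromosome); gaps are tolerated with a warning, overlaps are
    an error.  Fragment ids are unique genome-wide and baits are a subset
    of them.
    """

    fragments: pd.DataFrame
    bait_ids: frozenset
    bait_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.fragments
        self._mid = pd.Series(
            ((f["start"].to_numpy() + f["end"].to_numpy()) / 2.0),
            index=f["id"].to_numpy(),
        )
        self._chrom = pd.Series(f["chrom"].to_numpy(), index=f["id"].to_numpy())

    # -- lookups -----------------------------------------------------------
    def midpoint(self, ids) -> np.ndarray:
        return self._mid.loc[np.asarray(ids)].to_numpy()

    def chrom(self, ids) -> np.ndarray:
        return self._chrom.loc[np.asarray(ids)].to_numpy()

    def length(self, ids) -> np.ndarray:
        f = self.fragments.set_index("id")
        sub = f.loc[np.asarray(ids)]
        return (sub["end"] - sub["start"] + 1).to_numpy()

    def distance(self, bait_ids, other_ids) -> np.ndarray:
        """Midpoint distance in bp; NaN for trans (different chromosome)."""
        d = np.abs(self.midpoint(bait_ids) - self.midpoint(other_ids))
        trans = self.chrom(bait_ids) != self.chrom(other_ids)
        return np.where(trans, np.nan, d)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_baits(self) -> int:
        return len(self.bait_ids)


@dataclass
class InteractionTable:
    """Per-replicate pairwise read counts between baits and other ends.

    ``records`` columns: ``bait_id``, ``other_id``, ``count``,
    ``distance_bp`` (NaN for trans pairs), ``trans`` (bool).
    """

    replicate_id: str
    records: pd.DataFrame

    @property
    def cis(self) -> pd.DataFrame:
        return self.records[~self.records["trans"]]

    @property
    def trans(self) -> pd.DataFrame:
        return self.records[self.records["trans"]]


# ---------------------------------------------------------------------------
# fragment maps
# ---------------------------------------------------------------------------

def read_fragment_map(rmap_path, baitmap_path) -> FragmentMap:
    """Parse and validate an rmap/baitmap pair.

    Raises :class:`ParseError` (naming the offending line) on duplicate
    ids, overlapping fragments, or a bait id absent from the rmap.
    Non-contiguous fragments (gaps in the tiling) are reported as a
    warning with their line numbers, not an error.
    """
    try:
        rmap = pd.read_csv(
            rmap_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "id"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "id": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{rmap_path}: malformed rmap: {exc}") from exc
    if rmap.empty:
        raise ParseError(f"{rmap_path}: no fragments")

    dup = rmap["id"].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 1
        raise ParseError(
            f"{rmap_path}: duplicate fragment id {rmap['id'][dup].iloc[0]} at line {line}"
        )
    if (rmap["end"] < rmap["start"]).any():
        bad = int((rmap["end"] < rmap["start"]).idxmax()) + 1
        raise ParseError(f"{rmap_path}: end < start at line {bad}")

    rmap = rmap.reset_index().rename(columns={"index": "_line"})
    rmap["_line"] += 1
    rmap = rmap.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    gaps = []
    for _, grp in rmap.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lines = grp["_line"].to_numpy()
        overlap = starts[1:] <= ends[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            raise ParseError(
                f"{rmap_path}: overlapping fragments at lines "
                f"{lines[i]} and {lines[i + 1]}"
            )
        gap = starts[1:] != ends[:-1] + 1
        gaps.extend(lines[1:][gap].tolist())
    if gaps:
        warnings.warn(
            f"{rmap_path}: {len(gaps)} non-contiguous fragment(s) at lines {gaps[:10]}",
            stacklevel=2,
        )

    try:
        bmap = pd.read_csv(
            baitmap_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "id", "name"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "id": np.int64, "name": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{baitmap_path}: malformed baitmap: {exc}") from exc
    known = set(rmap["id"])
    for line0, bid in enumerate(bmap["id"], start=1):
        if bid not in known:
            raise ParseError(
                f"{baitmap_path}: bait id {bid} at line {line0} absent from rmap"
            )
    fragments = rmap.drop(columns=["_line"])
    return FragmentMap(
        fragments=fragments,
        bait_ids=frozenset(bmap["id"]),
        bait_names=dict(zip(bmap["id"], bmap["name"])),
    )


def write_fragment_map(fmap: FragmentMap, rmap_path, baitmap_path) -> None:
    fmap.fragments[["chrom", "start", "end", "id"]].to_csv(
        rmap_path, sep="\t", header=False, index=False
    )
    baits = fmap.fragments[fmap.fragments["id"].isin(fmap.bait_ids)].copy()
    baits["name"] = [fmap.bait_names.get(i, f"bait_{i}") for i in baits["id"]]
    baits[["chrom", "start", "end", "id", "name"]].to_csv(
        baitmap_path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_interactions(path, fmap: FragmentMap, replicate_id: str | None = None,
                      ) -> InteractionTable:
    """Parse a chinput-like count table and validate it against ``fmap``.

    Rows whose stored distance disagrees with the map-derived midpoint
    distance by more than 1 bp are an error; an empty/NA distSign flags a
    trans pair.  Nothing is silently dropped.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["baitID", "otherEndID", "N", "otherEndLen", "distSign"],
            dtype={"baitID": np.int64, "otherEndID": np.int64, "N": np.int64,
                   "otherEndLen": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed count table: {exc}") from exc
    if raw.empty:
        raise ParseError(f"{path}: no records")

    known = set(fmap.fragments["id"])
    for col in ("baitID", "otherEndID"):
        unknown = ~raw[col].isin(known)
        if unknown.any():
            line = int(unknown.idxmax()) + 1
            raise ParseError(
                f"{path}: unknown fragment id {raw[col][unknown].iloc[0]} "
                f"at line {line}"
            )
    not_bait = ~raw["baitID"].isin(fmap.bait_ids)
    if not_bait.any():
        line = int(not_bait.idxmax()) + 1
        raise ParseError(
            f"{path}: baitID {raw['baitID'][not_bait].iloc[0]} at line {line} "
            "is not a bait"
        )
    if (raw["N"] < 0).any():
        line = int((raw["N"] < 0).idxmax()) + 1
        raise ParseError(f"{path}: negative count at line {line}")

    dist_sign = pd.to_numeric(raw["distSign"], errors="coerce")
    map_dist = fmap.distance(raw["baitID"].to_numpy(), raw["otherEndID"].to_numpy())
    trans = np.isnan(map_dist)
    stored_trans = dist_sign.isna().to_numpy()
    if (trans != stored_trans).any():
        line = int(np.argmax(trans != stored_trans)) + 1
        raise ParseError(f"{path}: cis/trans flag disagrees with map at line {line}")
    mismatch = ~trans & (np.abs(np.abs(dist_sign.to_numpy()) - map_dist) > 1.0)
    if mismatch.any():
        line = int(np.argmax(mismatch)) + 1
        raise ParseError(
            f"{path}: stored distance disagrees with map by > 1 bp at line {line}"
        )
    # The sign of distSign (other end up/downstream of bait) is not used:
    # distances are unsigned internally.
    logger.debug("%s: discarding distSign orientation, keeping |distance|", path)

    records = pd.DataFrame(
        {
            "bait_id": raw["baitID"].to_numpy(),
            "other_id": raw["otherEndID"].to_numpy(),
            "count": raw["N"].to_numpy(),
            "distance_bp": map_dist,
            "trans": trans,
        }
    )
    if replicate_id is None:
        replicate_id = str(path)
    return InteractionTable(replicate_id=replicate_id, records=records)


def write_interactions(table: InteractionTable, path, fmap: FragmentMap) -> None:
    rec = table.records
    signed = fmap.midpoint(rec["other_id"].to_numpy()) - fmap.midpoint(
        rec["bait_id"].to_numpy()
    )
    out = pd.DataFrame(
        {
            "baitID": rec["bait_id"],
            "otherEndID": rec["other_id"],
            "N": rec["count"],
            "otherEndLen": fmap.length(rec["other_id"].to_numpy()),
            "distSign": [
                "NA" if t else str(int(round(s)))
                for t, s in zip(rec["trans"], signed)
            ],
        }
    )
    with open(path, "w") as fh:
        fh.write("# baitID\totherEndID\tN\totherEndLen\tdistSign\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# scored output
# ---------------------------------------------------------------------------

_SCORED_COLS = ["bait_id", "other_id", "distance_bp", "count", "log_p", "weight", "score"]


def _fmt6(x: float) -> str:
    return np.format_float_positional(float(x), precision=6, unique=False,
                                      fractional=False)


def write_scored_interactions(scored: pd.DataFrame, path, fmt: str = "tabular",
                              fmap: FragmentMap | None = None) -> None:
    """Write a directed scored-interaction table.

    ``tabular`` is a TSV with log_p, weight and score at 6 significant
    digits; ``bed-pair`` emits both anchors' coordinates (0-based
    half-open) with the score in the score column and requires ``fmap``.
    """
    if fmt == "tabular":
        with open(path, "w") as fh:
            fh.write("\t".join(_SCORED_COLS) + "\n")
            for row in scored.itertuples(index=False):
                fh.write(
                    f"{int(row.bait_id)}\t{int(row.other_id)}\t"
                    f"{row.distance_bp:.0f}\t{int(row.count)}\t"
                    f"{_fmt6(row.log_p)}\t{_fmt6(row.weight)}\t{_fmt6(row.score)}\n"
                )
    elif fmt == "bed-pair":
        if fmap is None:
            raise ValueError("bed-pair output requires a FragmentMap")
        frags = fmap.fragments.set_index("id")
        with open(path, "w") as fh:
            for row in scored.itertuples(index=False):
                a = frags.loc[int(row.bait_id)]
                b = frags.loc[int(row.other_id)]
                name = f"{int(row.bait_id)}_{int(row.other_id)}"
                fh.write(
                    f"{a.chrom}\t{a.start - 1}\t{a.end}\t"
                    f"{b.chrom}\t{b.start - 1}\t{b.end}\t"
                    f"{name}\t{_fmt6(row.score)}\n"
                )
    else:
        raise ValueError(f"unknown scored-output format: {fmt!r}")


def read_scored_interactions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SCORED_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df
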