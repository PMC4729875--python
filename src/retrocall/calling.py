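"""Junction-read insertion calling.

Amplicon reads are collapsed to unique amplicons (distinct genomic alignment
start per junction side, family and sample), single-linkage clustered along
each chromosome, and clusters are reported as insertion calls under the
survey's minimum evidence rule: at least two unique amplicons whose alignment
starts are separated by >= 5 nt.  Duplicate reads never count towards the
threshold, however many there are.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .consensus import ConsensusLibrary
from .simulate import READ_LENGTH

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 200        # single-linkage clustering window, bases
DEFAULT_MIN_UNIQUE = 2      # reporting threshold: unique amplicons
DEFAULT_MIN_SEPARATION = 5  # reporting threshold: max pairwise start distance
DEFAULT_CATALOG_WINDOW = 100

UNIQUE_KEY = ["sample", "chrom", "start", "side", "family"]

CALL_COLUMNS = ["call_id", "sample", "chrom", "family", "subfamily",
                "junction5", "junction3", "position", "n_unique",
                "max_separation", "catalog_status"]


def collapse_duplicates(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates to unique amplicons with a multiplicity count.

    Uniqueness is (sample, chromosome, alignment start, junction side,
    family); multiplicity is the number of collapsed reads.
    """
    if reads.empty:
        return pd.DataFrame(columns=UNIQUE_KEY + ["multiplicity", "diag"])
    gb = reads.groupby(UNIQUE_KEY, as_index=False)
    if "diag" in reads.columns:
        uniques = gb.agg(multiplicity=("read_id", "size"), diag=("diag", "first"))
    else:
        uniques = gb.agg(multiplicity=("read_id", "size"))
    return uniques.sort_values(UNIQUE_KEY, kind="mergesort").reset_index(drop=True)


def cluster_amplicons(uniques: pd.DataFrame, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Single-linkage clustering of unique amplicons along the genome.

    Consecutive same-sample, same-chromosome, same-family amplicons whose
    starts are within ``window`` merge transitively.  Returns the input with a
    ``cluster`` column; every unique amplicon belongs to exactly one cluster.
    """
    if window < 0:
        raise ValueError("clustering window must be non-negative")
    if uniques.empty:
        out = uniques.copy()
        out["cluster"] = pd.Series(dtype=int)
        return out
    u = uniques.sort_values(["sample", "family", "chrom", "start"],
                            kind="mergesort").reset_index(drop=True)
    key = u[["sample", "family", "chrom"]].apply(tuple, axis=1)
    new_group = (key != key.shift()).to_numpy()
    gap = u["start"].diff().to_numpy()
    breaks = new_group | (gap > window)
    u["cluster"] = np.cumsum(breaks) - 1
    return u


def _side_junction(members: pd.DataFrame) -> int:
    """Maximum-multiplicity member start; ties break to the smallest start."""
    m = members.sort_values(["multiplicity", "start"],
                            ascending=[False, True], kind="mergesort")
    best_mult = m.iloc[0]["multiplicity"]
    return int(m[m["multiplicity"] == best_mult]["start"].min())


def call_insertions(clustered: pd.DataFrame,
                    min_unique: int = DEFAULT_MIN_UNIQUE,
                    min_separation: int = DEFAULT_MIN_SEPARATION,
                    library: ConsensusLibrary | None = None,
                    read_length: int = READ_LENGTH) -> pd.DataFrame:
    """Emit insertion calls from clustered unique amplicons.

    A cluster is reported iff it holds >= ``min_unique`` unique amplicons
    whose maximum pairwise start separation is >= ``min_separation``.  The
    junction coordinate per side is the maximum-multiplicity member start
    (ties to the 5'-most).  ``position`` is the insertion-point estimate used
    for matching: the 3' junction start when present, else the 5' junction
    start shifted by the read length.
    """
    rows = []
    if clustered.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    for cid, members in clustered.groupby("cluster"):
        n_unique = len(members)
        max_sep = int(members["start"].max() - members["start"].min())
        if n_unique < min_unique or max_sep < min_separation:
            continue
        fam, sub = assign_family_subfamily(members, library)
        j5 = j3 = None
        m5 = members[members["side"] == "5p"]
        m3 = members[members["side"] == "3p"]
        if len(m5):
            j5 = _side_junction(m5)
        if len(m3):
            j3 = _side_junction(m3)
        position = j3 if j3 is not None else j5 + read_length
        rows.append({
            "call_id": f"call{len(rows) + 1}",
            "sample": members.iloc[0]["sample"],
            "chrom": members.iloc[0]["chrom"],
            "family": fam, "subfamily": sub,
            "junction5": -1 if j5 is None else j5,
            "junction3": -1 if j3 is None else j3,
            "position": position, "n_unique": n_unique,
            "max_separation": max_sep, "catalog_status": "novel",
        })
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(["sample", "chrom", "position"],
                             kind="mergesort").reset_index(drop=True)


def assign_family_subfamily(members: pd.DataFrame,
                            library: ConsensusLibrary | None) -> tuple[str, str]:
    """Family by majority vote; subfamily by diagnostic-position matches.

    Ties at either level resolve to ``"unresolved"`` at the subfamily level.
    """
    fam_counts = members["family"].value_counts()
    family = fam_counts.index[0]
    if library is None:
        return family, "unresolved"
    if family not in library.families:
        raise ValueError(f"unknown family label {family!r}")
    if "diag" not in members.columns or members["diag"].isna().all():
        return family, "unresolved"
    observed = members["diag"].mode().iloc[0]
    scores = {}
    for sub in library.subfamilies(family):
        ref = library.diag_bases(family, sub)
        scores[sub] = sum(a == b for a, b in zip(observed, ref))
    best = max(scores.values())
    winners = [s for s, v in scores.items() if v == best]
    return family, (winners[0] if len(winners) == 1 else "unresolved")


def match_catalog(calls: pd.DataFrame, catalog: pd.DataFrame,
                  match_window: int = DEFAULT_CATALOG_WINDOW) -> pd.DataFrame:
    """Label each call ``known`` or ``novel`` against a catalog BED table.

    A call is known iff a same-family catalog entry lies within
    +/- ``match_window`` of its position.  Malformed catalog records are
    skipped with a logged warning.
    """
    calls = calls.copy()
    entries = []
    skipped = 0
    if catalog is not None:
        for _, rec in catalog.iterrows():
            try:
                start = int(rec["start"])
                end = int(rec["end"])
                if start > end or start < 0:
                    raise ValueError("start > end")
                entries.append((str(rec["chrom"]), start, str(rec["name"])))
            except (KeyError, TypeError, ValueError) as exc:
                skipped += 1
                logger.warning("skipping malformed catalog record %r: %s",
                               dict(rec), exc)
    if skipped:
        logger.warning("skipped %d malformed catalog records", skipped)
    status = []
    for _, call in calls.iterrows():
        known = any(chrom == call["chrom"] and fam == call["family"]
                    and abs(start - int(call["position"])) <= match_window
                    for chrom, start, fam in entries)
        status.append("known" if known else "novel")
    calls["catalog_status"] = status
    return calls


def run_caller(reads: pd.DataFrame, window: int = DEFAULT_WINDOW,
               min_unique: int = DEFAULT_MIN_UNIQUE,
               min_separation: int = DEFAULT_MIN_SEPARATION,
               catalog: pd.DataFrame | None = None,
               match_window: int = DEFAULT_CATALOG_WINDOW,
               library: ConsensusLibrary | None = None) -> pd.DataFrame:
    """Full calling pass: collapse -> cluster -> threshold -> catalog."""
    uniques = collapse_duplicates(reads)
    clustered = cluster_amplicons(uniques, window=window)
    calls = call_insertions(clustered, min_unique=min_unique,
                            min_separation=min_separation, library=library)
    if catalog is not None:
        calls = match_catalog(calls, catalog, match_window=match_window)
    return calls
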