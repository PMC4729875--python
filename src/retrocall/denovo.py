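"""De novo annotation of insertion calls in pluripotent samples.

A call made in a pluripotent (hiPSC/hESC) sample is labelled *de novo* only
if it survives a four-filter cascade: it must not be (i) present in a known
non-reference insertion catalog, (ii) found in the matched parental sample,
(iii) found in an earlier passage of the same hESC line, or (iv) found in
more than one pluripotent cell line.  Presence in a *later* passage only is
compatible with de novo status (an insertion acquired during cultivation),
and two passages of one line count as a single line for the recurrence
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

FILTERS = ("catalog", "parental", "earlier_passage", "recurrent_across_lines")

DEFAULT_MATCH_WINDOW = 100  # bases; shared with catalog matching


@dataclass
class SampleInfo:
    role: str                      # 'parental' | 'hipsc' | 'hesc'
    line: str
    passage: int | None = None
    parent_sample: str | None = None


@dataclass
class CohortDesign:
    """Samples, their roles and lineage (parental -> derived, passage order)."""

    samples: dict[str, SampleInfo] = field(default_factory=dict)

    def __post_init__(self):
        for name, info in self.samples.items():
            if info.role not in ("parental", "hipsc", "hesc"):
                raise ValueError(f"unknown role {info.role!r} for sample {name!r}")
            if info.parent_sample is not None:
                parent = self.samples.get(info.parent_sample)
                if parent is None:
                    raise ValueError(
                        f"sample {name!r} references unknown parent "
                        f"{info.parent_sample!r}")
                if parent.parent_sample is not None:
                    raise ValueError("lineage deeper than parental -> derived")

    def pluripotent_samples(self) -> list[str]:
        return [s for s, i in self.samples.items() if i.role != "parental"]

    def earlier_passages(self, sample: str) -> list[str]:
        """Samples of the same line with a strictly earlier passage number."""
        info = self.samples[sample]
        if info.passage is None:
            return []
        return [s for s, i in self.samples.items()
                if s != sample and i.line == info.line
                and i.passage is not None and i.passage < info.passage]

    @classmethod
    def from_dict(cls, data: dict) -> "CohortDesign":
        samples = {name: SampleInfo(**info) for name, info in data["samples"].items()}
        return cls(samples=samples)


@dataclass
class FilterVerdict:
    call_id: str
    sample: str
    de_novo: bool
    failed: tuple[str, ...]


def cross_sample_match(call_a, call_b, match_window: int = DEFAULT_MATCH_WINDOW) -> bool:
    """True iff two calls are the same family on the same chromosome within
    +/- ``match_window`` of one another."""
    return (call_a["family"] == call_b["family"]
            and call_a["chrom"] == call_b["chrom"]
            and abs(int(call_a["position"]) - int(call_b["position"])) <= match_window)


def _match_any(call, calls: pd.DataFrame, window: int) -> bool:
    if calls.empty:
        return False
    sub = calls[(calls["family"] == call["family"])
                & (calls["chrom"] == call["chrom"])]
    if sub.empty:
        return False
    return bool((sub["position"].sub(int(call["position"])).abs() <= window).any())


def annotate_de_novo(calls: pd.DataFrame, catalog: pd.DataFrame,
                     design: CohortDesign,
                     match_window: int = DEFAULT_MATCH_WINDOW) -> pd.DataFrame:
    """Apply the four-filter cascade to every pluripotent-sample call.

    ``calls`` needs columns call_id, sample, chrom, position, family;
    ``catalog`` needs chrom, start, name (family).  Returns one row per
    pluripotent call with boolean columns per filter and a ``de_novo`` flag
    (true iff no filter failed).
    """
    for s in calls["sample"].unique():
        if s not in design.samples:
            raise ValueError(f"sample {s!r} absent from cohort design")
    cat = pd.DataFrame(columns=["family", "chrom", "position"])
    if catalog is not None and len(catalog):
        cat = pd.DataFrame({"family": catalog["name"],
                            "chrom": catalog["chrom"],
                            "position": catalog["start"].astype(int)})
    by_sample = {s: g for s, g in calls.groupby("sample")}
    rows = []
    for sample in design.pluripotent_samples():
        info = design.samples[sample]
        own = by_sample.get(sample)
        if own is None:
            continue
        parental_calls = (by_sample.get(info.parent_sample, pd.DataFrame())
                          if info.parent_sample else pd.DataFrame())
        earlier = (design.earlier_passages(sample) if info.role == "hesc" else [])
        other_lines = {design.samples[s].line: by_sample.get(s) for s in
                       design.pluripotent_samples()
                       if design.samples[s].line != info.line}
        for _, call in own.iterrows():
            failed = []
            if _match_any(call, cat, match_window):
                failed.append("catalog")
            if len(parental_calls) and _match_any(call, parental_calls, match_window):
                failed.append("parental")
            for s in earlier:
                other = by_sample.get(s)
                if other is not None and _match_any(call, other, match_window):
                    failed.append("earlier_passage")
                    break
            for line_calls in other_lines.values():
                if line_calls is not None and _match_any(call, line_calls,
                                                         match_window):
                    failed.append("recurrent_across_lines")
                    break
            rows.append({"call_id": call["call_id"], "sample": sample,
                         "chrom": call["chrom"], "position": call["position"],
                         "family": call["family"],
                         **{f: (f in failed) for f in FILTERS},
                         "de_novo": not failed})
    return pd.DataFrame(rows)
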