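"""Classify exact sequence tags (sOTUs) against a panel of known isolates.

The classification rule is deliberately strict: an sOTU is assigned an
isolate label only when its tag is *identical* to a reference sequence over
the trim length (150 bp read-1 fragments by default).  Everything else is a
"background contaminant" — reagent/consumable DNA that matches no isolate
placed on the plate.  Near-matches (1-2 edits from a reference, typically
denoiser artifacts) are surfaced as a diagnostic column but never change
the category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import edlib
import pandas as pd

from .errors import AmbiguousPanelError, ClassificationError, PanelError
from .table import FeatureTable

DEFAULT_TRIM_LENGTH = 150
_VALID_BASES = frozenset("ACGT")


class Category(str, Enum):
    SOURCE = "SOURCE"
    SINK = "SINK"
    CONTROL = "CONTROL"
    BACKGROUND = "BACKGROUND"


@dataclass(frozen=True)
class ReferenceSequence:
    """One reference sequence: an isolate label, its experimental role, and
    a read-1-orientation DNA string.  A label may own several sequences
    (multiple rRNA operons in one genome)."""

    label: str
    role: Category
    sequence: str

    def __post_init__(self) -> None:
        if self.role is Category.BACKGROUND:
            raise PanelError("panel entries cannot have role BACKGROUND")
        if not self.sequence or not set(self.sequence) <= _VALID_BASES:
            raise PanelError(
                f"reference {self.label!r} is not an uppercase ACGT string"
            )


@dataclass
class ReferencePanel:
    """Trimmed isolate references used for exact-match classification."""

    entries: list[ReferenceSequence]
    trim_length: int = DEFAULT_TRIM_LENGTH

    def __post_init__(self) -> None:
        if self.trim_length < 1:
            raise PanelError("trim_length must be >= 1")
        short = [e.label for e in self.entries if len(e.sequence) < self.trim_length]
        if short:
            raise PanelError(
                f"reference sequences shorter than trim_length {self.trim_length}: "
                f"{sorted(set(short))}"
            )
        seen: dict[str, ReferenceSequence] = {}
        for e in self.entries:
            key = e.sequence[: self.trim_length]
            prev = seen.get(key)
            if prev is not None:
                if prev.label != e.label:
                    raise AmbiguousPanelError(
                        f"trimmed sequence shared by labels {prev.label!r} and "
                        f"{e.label!r}"
                    )
                raise PanelError(
                    f"duplicate trimmed sequence for label {e.label!r}"
                )
            seen[key] = e
        self._lookup: dict[str, ReferenceSequence] = seen

    @property
    def labels(self) -> list[str]:
        out: dict[str, None] = {}
        for e in self.entries:
            out.setdefault(e.label, None)
        return list(out)

    def labels_with_role(self, role: Category) -> list[str]:
        out: dict[str, None] = {}
        for e in self.entries:
            if e.role is role:
                out.setdefault(e.label, None)
        return list(out)

    def lookup(self, tag: str) -> ReferenceSequence | None:
        """Exact-match a trimmed tag against the panel; None = background."""
        return self._lookup.get(tag[: self.trim_length])

    # ------------------------------------------------------------------ I/O
    # FASTA headers follow "label|role", e.g. ">source_03|SOURCE".
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, e in enumerate(self.entries):
                fh.write(f">{e.label}|{e.role.value} seq{i}\n{e.sequence}\n")

    @classmethod
    def from_fasta(
        cls, path: str | Path, trim_length: int = DEFAULT_TRIM_LENGTH
    ) -> "ReferencePanel":
        entries: list[ReferenceSequence] = []
        header: str | None = None
        chunks: list[str] = []

        def flush() -> None:
            if header is None:
                return
            name = header.split()[0]
            if "|" not in name:
                raise PanelError(f"FASTA header {header!r} is not 'label|role'")
            label, role = name.rsplit("|", 1)
            try:
                role_cat = Category(role.upper())
            except ValueError:
                raise PanelError(f"unknown panel role {role!r} in {header!r}") from None
            entries.append(
                ReferenceSequence(label, role_cat, "".join(chunks).upper())
            )

        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    header = line[1:]
                    chunks = []
                else:
                    chunks.append(line)
            flush()
        if not entries:
            raise PanelError(f"no sequences found in {path}")
        return cls(entries=entries, trim_length=trim_length)


@dataclass(frozen=True)
class SotuCall:
    category: Category
    label: str | None  # None iff BACKGROUND


@dataclass
class SotuClassification:
    """Mapping of every sOTU in a (filtered) table to its category."""

    calls: dict[str, SotuCall] = field(default_factory=dict)

    def __getitem__(self, sotu_id: str) -> SotuCall:
        return self.calls[sotu_id]

    def __contains__(self, sotu_id: str) -> bool:
        return sotu_id in self.calls

    def __len__(self) -> int:
        return len(self.calls)

    def sotus_in_category(self, category: Category) -> list[str]:
        return [s for s, c in self.calls.items() if c.category is category]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sotu_id": list(self.calls),
                "category": [c.category.value for c in self.calls.values()],
                "label": [c.label or "" for c in self.calls.values()],
            }
        ).set_index("sotu_id")


def remove_singletons(table: FeatureTable) -> FeatureTable:
    """Drop sOTUs whose total count across the whole data set equals 1.

    The sample set is unchanged and no rarefaction is performed; read counts
    are left as observed so contamination fractions stay interpretable.
    """
    totals = table.counts.sum(axis=0)
    keep = totals[totals != 1].index
    return FeatureTable(table.counts.loc[:, keep].copy(), metadata=table.metadata)


def classify_sotus(
    table: FeatureTable,
    panel: ReferencePanel,
    near_match_max_dist: int = 2,
) -> SotuClassification:
    """Assign every sOTU in ``table`` a category via exact panel matching.

    sOTU identifiers must be the exact sequence tags.  A tag gets a panel
    label iff it is identical to a reference over the panel's trim length;
    otherwise it is BACKGROUND.  Classification ignores counts entirely.
    """
    calls: dict[str, SotuCall] = {}
    too_short = [
        s for s in table.sotu_ids if len(s) < panel.trim_length
    ]
    if too_short:
        raise ClassificationError(
            f"{len(too_short)} sOTU tag(s) shorter than trim_length "
            f"{panel.trim_length}: {too_short[:5]}"
        )
    for sotu in table.sotu_ids:
        hit = panel.lookup(sotu)
        if hit is not None:
            calls[sotu] = SotuCall(hit.role, hit.label)
        else:
            calls[sotu] = SotuCall(Category.BACKGROUND, None)
    return SotuClassification(calls=calls)


def near_match_report(
    table: FeatureTable, panel: ReferencePanel, max_dist: int = 2
) -> pd.DataFrame:
    """Edit distance from each BACKGROUND tag to its nearest reference.

    Purely diagnostic: tags within ``max_dist`` edits of a reference are
    often denoiser artifacts, but the strict exact-match rule still calls
    them background.
    """
    refs = [(e.label, e.sequence[: panel.trim_length]) for e in panel.entries]
    rows = []
    for sotu in table.sotu_ids:
        tag = sotu[: panel.trim_length]
        if panel.lookup(sotu) is not None:
            continue
        best_label, best_dist = None, None
        for label, ref in refs:
            d = edlib.align(tag, ref, task="distance", k=max_dist)["editDistance"]
            if d != -1 and (best_dist is None or d < best_dist):
                best_label, best_dist = label, d
        if best_dist is not None:
            rows.append(
                {"sotu_id": sotu, "nearest_label": best_label, "edit_distance": best_dist}
            )
    return pd.DataFrame(rows, columns=["sotu_id", "nearest_label", "edit_distance"])
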