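"""Container for simulated (or ingested) recall corpora."""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass, field

from .design import TrialList

__all__ = ["TrialRecord", "Corpus"]


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    participant: int
    condition: str
    trial: TrialList
    response: tuple[int, ...]


@dataclass
class Corpus:
    """An ordered collection of scored-ready trials.

    ``process`` records the generating process for synthetic corpora
    (``"compression"`` or ``"redintegration"``); ingested data leave it None.
    """

    records: list[TrialRecord] = field(default_factory=list)
    master_seed: int | None = None
    process: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.records)

    def pairs(self) -> Iterator[tuple[TrialList, tuple[int, ...]]]:
        """(target, response) pairs in trial order — the scoring interface."""
        return ((r.trial, r.response) for r in self.records)

    def trial_ids(self) -> list[int]:
        return [r.trial_id for r in self.records]

    def conditions(self) -> list[str]:
        return sorted({r.condition for r in self.records})
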