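"""Plain-text serialisation: trials/responses CSV dialect, score tables,
parameter and generator configuration files.

Trials CSV: one row per word with columns
``trial_id, participant, condition, chunk_index, chunk_size, word_position,
word_id, is_prelearned``.  Responses CSV: one row per output position with
``trial_id, output_position, word_id`` where an omission is written as the
literal string ``blank``.  Files carry a ``# master_seed=...`` stamp line;
readers skip ``#`` comments.
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .corpus import Corpus, TrialRecord
from .design import ChunkToken, TrialList
from .model import ModelParams
from .scoring import BLANK

__all__ = [
    "corpus_to_frames",
    "frames_to_corpus",
    "write_corpus",
    "read_corpus",
    "write_table",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]


def corpus_to_frames(corpus: Corpus) -> tuple[pd.DataFrame, pd.DataFrame]:
    trial_rows = []
    response_rows = []
    for rec in corpus:
        position = 1
        for ci, token in enumerate(rec.trial.tokens, start=1):
            for w in token.words:
                trial_rows.append(
                    (
                        rec.trial_id,
                        rec.participant,
                        rec.condition,
                        ci,
                        token.size,
                        position,
                        w,
                        token.is_prelearned,
                    )
                )
                position += 1
        for op, w in enumerate(rec.response, start=1):
            response_rows.append(
                (rec.trial_id, op, "blank" if w == BLANK else w)
            )
    trials = pd.DataFrame(
        trial_rows,
        columns=[
            "trial_id",
            "participant",
            "condition",
            "chunk_index",
            "chunk_size",
            "word_position",
            "word_id",
            "is_prelearned",
        ],
    )
    responses = pd.DataFrame(
        response_rows, columns=["trial_id", "output_position", "word_id"]
    )
    return trials, responses


def frames_to_corpus(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    master_seed: int | None = None,
    process: str | None = None,
) -> Corpus:
    resp_by_trial: dict[int, tuple[int, ...]] = {}
    for tid, grp in responses.groupby("trial_id"):
        grp = grp.sort_values("output_position")
        resp_by_trial[int(tid)] = tuple(
            BLANK if str(w) == "blank" else int(w) for w in grp.word_id
        )
    records = []
    for tid, grp in trials.groupby("trial_id", sort=True):
        grp = grp.sort_values("word_position")
        tokens = []
        for ci, chunk in grp.groupby("chunk_index", sort=True):
            tokens.append(
                ChunkToken(int(chunk.chunk_size.iloc[0]), tuple(int(w) for w in chunk.word_id))
            )
        trial = TrialList(tuple(tokens))
        tid = int(tid)
        if tid not in resp_by_trial:
            raise ValueError(f"no response rows for trial {tid}")
        records.append(
            TrialRecord(
                tid,
                int(grp.participant.iloc[0]),
                str(grp.condition.iloc[0]),
                trial,
                resp_by_trial[tid],
            )
        )
    return Corpus(records, master_seed=master_seed, process=process)


def _write_stamped(df: pd.DataFrame, path: Path, master_seed: int | None) -> None:
    with open(path, "w") as fh:
        if master_seed is not None:
            fh.write(f"# master_seed={master_seed}\n")
        df.to_csv(fh, index=False)


def write_corpus(corpus: Corpus, trials_path: str | Path, responses_path: str | Path) -> None:
    trials, responses = corpus_to_frames(corpus)
    _write_stamped(trials, Path(trials_path), corpus.master_seed)
    _write_stamped(responses, Path(responses_path), corpus.master_seed)


def read_corpus(
    trials_path: str | Path,
    responses_path: str | Path,
    **kwargs: Any,
) -> Corpus:
    trials = pd.read_csv(trials_path, comment="#")
    responses = pd.read_csv(responses_path, comment="#")
    return frames_to_corpus(trials, responses, **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, master_seed: int | None = None) -> None:
    """Write any result table as stamped CSV."""
    _write_stamped(df, Path(path), master_seed)


def params_to_dict(params: ModelParams) -> dict[str, Any]:
    return {f.name: getattr(params, f.name) for f in fields(ModelParams)}


def params_from_dict(d: dict[str, Any]) -> ModelParams:
    known = {f.name for f in fields(ModelParams)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown model parameters: {sorted(unknown)}")
    return ModelParams(**d)


def save_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    payload = params_to_dict(params)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_params(path: str | Path) -> ModelParams:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return params_from_dict(yaml.safe_load(text))
    return params_from_dict(json.loads(text))
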