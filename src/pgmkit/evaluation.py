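"""Question–answer scoring of the knowledge graph: recall, precision, F1.

A benchmark is a mapping question -> expected answer set; the graph's output
is a second mapping question -> returned answer set.  A question counts as
*correct* when its returned set matches its expected set under the chosen
match mode (one question = one unit, so 25 correct out of 30 expected and 28
answered gives recall 25/30 and precision 25/28).  F1 is the harmonic mean
of precision and recall — 0 when both are 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

from .graph import name_key

__all__ = ["EvalResult", "score_qa", "load_qa"]


@dataclass(frozen=True)
class EvalResult:
    n_expected: int
    n_returned: int
    n_correct: int
    unexpected_questions: tuple[str, ...] = ()

    @property
    def recall(self) -> float:
        return self.n_correct / self.n_expected if self.n_expected else 0.0

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_returned if self.n_returned else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "n_expected": self.n_expected,
            "n_returned": self.n_returned,
            "n_correct": self.n_correct,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }


def _norm_set(answers) -> frozenset[str]:
    if isinstance(answers, str):
        answers = [answers]
    return frozenset(name_key(str(a)) for a in answers if str(a).strip())


def score_qa(
    expected: Mapping[str, object],
    returned: Mapping[str, object],
    match_mode: str = "exact",
    overlap_threshold: float = 1.0,
) -> EvalResult:
    """Score returned answer sets against expected ones.

    ``match_mode="exact"`` requires set equality after name normalization;
    ``match_mode="overlap"`` accepts a Jaccard overlap >= ``overlap_threshold``.
    Questions answered but never asked count toward ``n_returned`` only and
    are reported in ``unexpected_questions``. Empty returned sets are treated
    as unanswered.
    """
    if match_mode not in ("exact", "overlap"):
        raise ValueError(f"unknown match mode: {match_mode!r}")
    exp = {q: _norm_set(a) for q, a in expected.items()}
    ret = {q: _norm_set(a) for q, a in returned.items()}
    ret = {q: a for q, a in ret.items() if a}

    n_correct = 0
    for q, answer in ret.items():
        want = exp.get(q)
        if want is None:
            continue
        if match_mode == "exact":
            ok = answer == want
        else:
            union = answer | want
            ok = bool(union) and len(answer & want) / len(union) >= overlap_threshold
        if ok:
            n_correct += 1
    return EvalResult(
        n_expected=len(exp),
        n_returned=len(ret),
        n_correct=n_correct,
        unexpected_questions=tuple(sorted(set(ret) - set(exp))),
    )


def load_qa(source: str | Path | IO[str]) -> dict[str, list[str]]:
    """Load a QA document: JSON object question -> answer list (or string)."""
    if isinstance(source, (str, Path)) and str(source) and Path(str(source)).is_file():
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    doc = json.loads(text)
    if not isinstance(doc, Mapping):
        raise ValueError("QA document must be a JSON object question -> answers")
    return {str(q): (a if isinstance(a, list) else [a]) for q, a in doc.items()}
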