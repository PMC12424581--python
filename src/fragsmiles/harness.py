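"""Predictor contract and reference predictors.

A predictor maps a source string to at most ``k`` ranked candidate strings
with non-increasing scores, mirroring beam-search output.  Training and
decoding of real seq2seq models are outside this package; the two
predictors here exist so the full prepare -> predict -> evaluate path is
exercisable and so evaluation metrics can be validated against configured
ground truth:

* :func:`memorizer_predictor` — returns the stored target for seen sources
  and nearest-neighbour targets (token-set overlap) otherwise;
* :func:`mock_predictor` — samples per-rank outcome categories
  (match / valid-but-wrong / a planted error class) with configured
  probabilities, for analytic metric-recovery tests.

An external model is plugged in by providing any object with the same
``name``/``notation``/``k``/``predict`` surface.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from typing import Callable

from .errors import ConfigError, UnreachableClassError
from .fixtures import corrupt, corrupt_to_valid_variant
from .notation import get_codec
from .reactions import TaskPair


@dataclass
class Predictor:
    name: str
    notation: str
    k: int
    _predict: Callable[[str], list[tuple[str, float]]] = field(repr=False)

    def predict(self, source: str) -> list[tuple[str, float]]:
        """Ranked (candidate, score) list, scores non-increasing, length <= k."""
        out = self._predict(source)[: self.k]
        return out

    def predict_strings(self, source: str) -> list[str]:
        return [cand for cand, _ in self.predict(source)]


def memorizer_predictor(
    train_pairs: list[TaskPair], k: int = 5, name: str = "memorizer"
) -> Predictor:
    """Oracle baseline: rank 1 is the stored target for seen sources; the
    remaining ranks (and unseen sources) are filled with the targets of the
    nearest stored sources by token-set Jaccard overlap."""
    if not train_pairs:
        raise ConfigError("memorizer needs a non-empty training set")
    notation = train_pairs[0].notation
    codec = get_codec(notation)
    store: dict[str, str] = {}
    token_sets: dict[str, frozenset] = {}
    for pair in train_pairs:
        store.setdefault(pair.source, pair.target)
        token_sets[pair.source] = frozenset(codec.tokenize(pair.source))

    sources = sorted(store)

    def _predict(source: str) -> list[tuple[str, float]]:
        query = frozenset(codec.tokenize(source))

        def jaccard(other: str) -> float:
            ts = token_sets[other]
            union = len(query | ts)
            return len(query & ts) / union if union else 0.0

        ranked = sorted(sources, key=lambda s: (-jaccard(s), s))
        out: list[tuple[str, float]] = []
        seen_targets: set[str] = set()
        if source in store:
            out.append((store[source], 1.0))
            seen_targets.add(store[source])
        for other in ranked:
            if len(out) >= k:
                break
            target = store[other]
            if target in seen_targets:
                continue
            seen_targets.add(target)
            out.append((target, jaccard(other)))
        # enforce non-increasing scores after the exact-hit bonus
        rescored = [
            (cand, score if i == 0 else min(score, out[i - 1][1]))
            for i, (cand, score) in enumerate(out)
        ]
        return rescored

    return Predictor(name=name, notation=notation, k=k, _predict=_predict)


#: outcome categories a rank profile may assign probability to
MATCH = "match"
WRONG_VALID = "wrong_valid"


def mock_predictor(
    references: dict[str, str],
    profile: list[dict[str, float]],
    notation: str,
    seed: int = 0,
    name: str = "mock",
) -> Predictor:
    """Configurable-outcome predictor over known references.

    ``references`` maps source strings to their true targets; ``profile``
    holds one dict per rank assigning probabilities to ``match``,
    ``wrong_valid`` and taxonomy error classes (each dict must sum to 1).
    Outcomes are sampled independently per record and rank, reproducibly
    under ``seed``.
    """
    for rank, probs in enumerate(profile):
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"rank {rank + 1} profile probabilities sum to {total}, not 1"
            )
    k = len(profile)
    cache: dict[tuple[str, str], str] = {}

    def _realize(target: str, category: str) -> str:
        if category == MATCH:
            return target
        key = (target, category)
        if key not in cache:
            # seed from content, not from the sampling stream, so cache
            # hits and misses leave the category draws untouched
            sub_seed = (
                seed * 0x9E3779B1
                + zlib.crc32(target.encode())
                + zlib.crc32(category.encode())
            ) & 0x7FFFFFFF
            if category == WRONG_VALID:
                cache[key] = corrupt_to_valid_variant(
                    target, notation, seed=sub_seed
                )
            else:
                cache[key] = corrupt(target, notation, category, seed=sub_seed)
        return cache[key]

    def _predict(source: str) -> list[tuple[str, float]]:
        if source not in references:
            raise ConfigError(f"mock predictor has no reference for {source!r}")
        target = references[source]
        # stable per-source stream: crc32 is process-independent (unlike hash())
        rng = random.Random(
            (seed * 0x9E3779B1 + zlib.crc32(source.encode())) & 0x7FFFFFFF
        )
        out = []
        for rank, probs in enumerate(profile):
            categories = list(probs)
            weights = [probs[c] for c in categories]
            category = rng.choices(categories, weights=weights, k=1)[0]
            try:
                cand = _realize(target, category)
            except UnreachableClassError:
                cand = target  # degrade to a match rather than crash
            out.append((cand, 1.0 / (rank + 1)))
        return out

    return Predictor(name=name, notation=notation, k=k, _predict=_predict)


def run_predictor(
    predictor: Predictor, sources: dict[str, str]
) -> dict[str, list[str]]:
    """Apply a predictor to ``{record_id: source}``; returns ranked
    candidate strings per record id (the evaluation input shape)."""
    return {
        rid: predictor.predict_strings(source)
        for rid, source in sources.items()
    }
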