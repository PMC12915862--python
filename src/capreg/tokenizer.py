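"""Overlapping-word pre-tokenization and byte-pair encoding for DNA.

A sequence S is cut into 8-nt words starting every 4 nt, so consecutive
words within one offset share exactly 4 nt; the cut is repeated at offsets
1, 2 and 3 so that a word starts at every position of S.  BPE is then
trained from single-character tokens by repeatedly merging the most
frequent adjacent token pair, never across word boundaries.  Every token
keeps its (offset, start, end) nucleotide span so attention peaks can be
mapped back onto the sequence.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "WordSequence",
    "BpeVocab",
    "Encoding",
    "make_words",
    "make_word_corpus",
    "bpe_train",
    "bpe_encode",
    "bpe_decode",
]

WORD_LEN = 8
STRIDE = 4
PAD, UNK = "<pad>", "<unk>"
BASE_ALPHABET = ("A", "C", "G", "T", "N")
#: characters that stay atomic: ambiguity codes never participate in merges
MERGEABLE = frozenset("ACGT")


@dataclass
class WordSequence:
    """8-nt words with their source spans (0-based half-open) and offsets."""

    words: list[str] = field(default_factory=list)
    spans: list[tuple[int, int]] = field(default_factory=list)
    offsets: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.words)

    def extend(self, other: "WordSequence") -> None:
        self.words.extend(other.words)
        self.spans.extend(other.spans)
        self.offsets.extend(other.offsets)


def make_words(sequence: str, offset: int = 0) -> WordSequence:
    """Words W_{k,i} = S[4k+i : 4k+i+8] for one offset i.

    Yields floor((|S| - 8 - i) / 4) + 1 words; an over-short sequence gives
    an empty list with a warning.
    """
    if offset not in (0, 1, 2, 3):
        raise ValueError(f"offset must be in 0..3, got {offset}")
    n = len(sequence)
    if n < WORD_LEN + offset:
        logger.warning("sequence of length %d too short for offset %d", n, offset)
        return WordSequence()
    count = (n - WORD_LEN - offset) // STRIDE + 1
    ws = WordSequence()
    for k in range(count):
        start = STRIDE * k + offset
        ws.words.append(sequence[start : start + WORD_LEN])
        ws.spans.append((start, start + WORD_LEN))
        ws.offsets.append(offset)
    return ws


def make_word_corpus(
    sequence: str, offsets: tuple[int, ...] = (0, 1, 2, 3)
) -> WordSequence:
    """Concatenated per-offset word lists, in the given offset order."""
    corpus = WordSequence()
    for off in offsets:
        corpus.extend(make_words(sequence, off))
    return corpus


@dataclass
class BpeVocab:
    """Ordered merge list plus a dense token <-> id table.

    ``merges[j]`` records the pair merged at step j together with its
    corpus frequency at merge time; replaying the merges in order on the
    training corpus reproduces the final token multiset.
    """

    merges: list[tuple[str, str, int]] = field(default_factory=list)
    tokens: list[str] = field(default_factory=lambda: [PAD, UNK, *BASE_ALPHABET])

    def __post_init__(self):
        self.token_to_id = {t: i for i, t in enumerate(self.tokens)}
        self._ranks = {(a, b): j for j, (a, b, _) in enumerate(self.merges)}

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def __len__(self) -> int:
        return len(self.tokens)

    def id_for(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"merges": [list(m) for m in self.merges], "tokens": self.tokens},
                fh,
            )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "BpeVocab":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            merges=[tuple(m) for m in d["merges"]], tokens=list(d["tokens"])
        )


@dataclass
class Encoding:
    """Token ids plus per-token (offset, start, end) nucleotide spans."""

    ids: list[int] = field(default_factory=list)
    spans: list[tuple[int, int]] = field(default_factory=list)
    offsets: list[int] = field(default_factory=list)
    word_index: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)


def _word_pairs(word: tuple[str, ...]):
    return zip(word, word[1:])


def bpe_train(word_corpus, num_merges: int) -> BpeVocab:
    """Learn a BPE vocabulary from scratch on a word corpus.

    Starts from single characters, then performs up to ``num_merges``
    greedy merges of the most frequent adjacent pair (frequency weighted by
    word frequency; overlapping occurrences each count).  Ties break to the
    lexicographically smallest pair; training stops early once no pair
    occurs at least twice.  Pairs touching an ambiguity code (any character
    outside {A,C,G,T}) are never merged.
    """
    if num_merges < 0:
        raise ValueError("num_merges must be >= 0")
    words = word_corpus.words if isinstance(word_corpus, WordSequence) else list(word_corpus)
    if not words:
        raise ValueError("empty word corpus")

    freqs: dict[str, int] = {}
    for w in words:
        freqs[w] = freqs.get(w, 0) + 1

    extra_chars = sorted({c for w in freqs for c in w} - set(BASE_ALPHABET))
    tokens = [PAD, UNK, *BASE_ALPHABET, *extra_chars]

    # word types as token tuples, with incremental pair bookkeeping
    wids = list(freqs)
    seqs: dict[int, tuple[str, ...]] = {i: tuple(wids[i]) for i in range(len(wids))}
    wfreq = {i: freqs[wids[i]] for i in range(len(wids))}

    def mergeable(pair: tuple[str, str]) -> bool:
        return all(set(t) <= MERGEABLE for t in pair)

    pair_counts: dict[tuple[str, str], int] = {}
    pair_wids: dict[tuple[str, str], set[int]] = {}
    for i, seq in seqs.items():
        for pair in _word_pairs(seq):
            if mergeable(pair):
                pair_counts[pair] = pair_counts.get(pair, 0) + wfreq[i]
                pair_wids.setdefault(pair, set()).add(i)

    merges: list[tuple[str, str, int]] = []
    for _ in range(num_merges):
        if not pair_counts:
            break
        best = min(pair_counts, key=lambda p: (-pair_counts[p], p))
        best_count = pair_counts[best]
        if best_count < 2:
            break
        a, b = best
        new_tok = a + b
        merges.append((a, b, best_count))
        tokens.append(new_tok)
        for i in list(pair_wids.get(best, ())):
            old = seqs[i]
            f = wfreq[i]
            for pair in _word_pairs(old):
                if pair in pair_counts:
                    pair_counts[pair] -= f
                    if pair_counts[pair] <= 0:
                        del pair_counts[pair]
                    s = pair_wids.get(pair)
                    if s is not None:
                        s.discard(i)
                        if not s:
                            del pair_wids[pair]
            new_seq = _merge_once(old, a, b)
            seqs[i] = new_seq
            for pair in _word_pairs(new_seq):
                if mergeable(pair):
                    pair_counts[pair] = pair_counts.get(pair, 0) + f
                    pair_wids.setdefault(pair, set()).add(i)
    return BpeVocab(merges=merges, tokens=tokens)


def _merge_once(seq: tuple[str, ...], a: str, b: str) -> tuple[str, ...]:
    """Replace (a, b) occurrences left-to-right by the concatenated token."""
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == a and seq[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return tuple(out)


def _segment_word(word: str, vocab: BpeVocab) -> tuple[str, ...]:
    """Segment one word by applying learned merges in rank order."""
    seq: tuple[str, ...] = tuple(word)
    ranks = vocab._ranks
    while len(seq) > 1:
        best_rank, best_pair = None, None
        for pair in _word_pairs(seq):
            r = ranks.get(pair)
            if r is not None and (best_rank is None or r < best_rank):
                best_rank, best_pair = r, pair
        if best_pair is None:
            break
        seq = _merge_once(seq, *best_pair)
    return seq


def bpe_encode(word_sequence: WordSequence, vocab: BpeVocab) -> Encoding:
    """Encode words independently (merges never cross word boundaries).

    Token spans are cut from each word's span by cumulative token length;
    characters absent from the vocabulary map to the unknown token but keep
    their true 1-character span.
    """
    cache: dict[str, tuple[str, ...]] = {}
    enc = Encoding()
    for widx, (word, (wstart, _), off) in enumerate(
        zip(word_sequence.words, word_sequence.spans, word_sequence.offsets)
    ):
        pieces = cache.get(word)
        if pieces is None:
            pieces = _segment_word(word, vocab)
            cache[word] = pieces
        pos = wstart
        for piece in pieces:
            enc.ids.append(vocab.id_for(piece))
            enc.spans.append((pos, pos + len(piece)))
            enc.offsets.append(off)
            enc.word_index.append(widx)
            pos += len(piece)
    return enc


def bpe_decode(encoding: Encoding, vocab: BpeVocab) -> list[str]:
    """Reassemble word strings by concatenating token strings per word."""
    words: dict[int, list[str]] = {}
    for tid, widx in zip(encoding.ids, encoding.word_index):
        if not (0 <= tid < len(vocab.tokens)):
            raise ValueError(f"unknown token id {tid}")
        words.setdefault(widx, []).append(vocab.tokens[tid])
    return ["".join(words[w]) for w in sorted(words)]
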