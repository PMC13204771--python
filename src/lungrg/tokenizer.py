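"""Byte-level byte-pair-encoding tokenizer.

A GPT-2-style byte-level BPE: text is UTF-8 encoded, split into
space-prefixed words, and merge rules learned by iteratively fusing the most
frequent adjacent symbol pair are applied greedily at encode time.  Ids
0..255 are the raw bytes, merged symbols follow, and a single special
``<|endoftext|>`` token doubles as beginning- and end-of-sequence marker —
by convention the last id of the configured vocabulary (50,256 for the full
GPT-2 vocabulary size).

The merge table is trained on the report corpus at hand and can be saved to
/ loaded from a JSON file; the decoder's embedding table size is a model
property and does not depend on how many merges were actually learned.
"""

from __future__ import annotations

import json
from collections import Counter
from typing import Dict, Iterable, List, Sequence, Tuple

GPT2_VOCAB = 50_257


def _words(text: str) -> List[bytes]:
    """Whitespace-aware word split; each non-initial word keeps its leading
    space so that detokenization is exact."""
    out: List[bytes] = []
    for i, w in enumerate(text.split(" ")):
        piece = (" " + w) if i > 0 else w
        if piece:
            out.append(piece.encode("utf-8"))
    return out


class ByteBPETokenizer:
    def __init__(self, merges: Sequence[Tuple[int, int]] = (),
                 vocab_size: int = GPT2_VOCAB):
        if vocab_size < 257:
            raise ValueError("vocab_size must cover 256 bytes + 1 special token")
        self.vocab_size = vocab_size
        self.special_id = vocab_size - 1
        self.merges: List[Tuple[int, int]] = [tuple(m) for m in merges]
        self._rebuild()

    def _rebuild(self):
        self.ranks: Dict[Tuple[int, int], int] = {
            m: i for i, m in enumerate(self.merges)}
        self.merge_id: Dict[Tuple[int, int], int] = {
            m: 256 + i for i, m in enumerate(self.merges)}
        # id -> byte string
        self.id_bytes: Dict[int, bytes] = {i: bytes([i]) for i in range(256)}
        for i, (a, b) in enumerate(self.merges):
            self.id_bytes[256 + i] = self.id_bytes[a] + self.id_bytes[b]

    # ----------------------------------------------------------------- train
    @classmethod
    def train(cls, corpus: Iterable[str], n_merges: int,
              vocab_size: int = GPT2_VOCAB) -> "ByteBPETokenizer":
        """Learn up to ``n_merges`` merge rules from a text corpus.

        Ties in pair frequency break on the lexicographically smaller pair,
        making training deterministic.
        """
        n_merges = min(n_merges, vocab_size - 257)
        word_freq: Counter = Counter()
        for text in corpus:
            for w in _words(text):
                word_freq[w] += 1
        seqs: Dict[bytes, List[int]] = {w: list(w) for w in word_freq}
        merges: List[Tuple[int, int]] = []
        next_id = 256
        for _ in range(n_merges):
            pairs: Counter = Counter()
            for w, seq in seqs.items():
                f = word_freq[w]
                for a, b in zip(seq, seq[1:]):
                    pairs[(a, b)] += f
            if not pairs:
                break
            best = max(pairs.items(), key=lambda kv: (kv[1], [-x for x in kv[0]]))
            pair, count = best
            if count < 2:
                break
            merges.append(pair)
            for w, seq in seqs.items():
                seqs[w] = _apply_merge(seq, pair, next_id)
            next_id += 1
        return cls(merges, vocab_size=vocab_size)

    # ---------------------------------------------------------------- encode
    def encode(self, text: str, add_special: bool = False) -> List[int]:
        ids: List[int] = []
        if add_special:
            ids.append(self.special_id)
        for w in _words(text):
            seq = list(w)
            while len(seq) > 1:
                ranked = [(self.ranks.get((a, b), None), i)
                          for i, (a, b) in enumerate(zip(seq, seq[1:]))]
                ranked = [(r, i) for r, i in ranked if r is not None]
                if not ranked:
                    break
                r, i = min(ranked)
                pair = (seq[i], seq[i + 1])
                seq = _apply_merge(seq, pair, self.merge_id[pair])
            ids.extend(seq)
        if add_special:
            ids.append(self.special_id)
        return ids

    def decode(self, ids: Sequence[int]) -> str:
        chunks = [self.id_bytes[i] for i in ids if i != self.special_id
                  and i in self.id_bytes]
        return b"".join(chunks).decode("utf-8", errors="replace")

    @property
    def n_symbols(self) -> int:
        """Number of ids actually producible (bytes + merges + special)."""
        return 256 + len(self.merges) + 1

    # ------------------------------------------------------------------- io
    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"vocab_size": self.vocab_size,
                       "merges": self.merges}, fh)

    @classmethod
    def load(cls, path: str) -> "ByteBPETokenizer":
        with open(path, encoding="utf-8") as fh:
            blob = json.load(fh)
        return cls([tuple(m) for m in blob["merges"]],
                   vocab_size=blob["vocab_size"])


def _apply_merge(seq: List[int], pair: Tuple[int, int], new_id: int
                 ) -> List[int]:
    out: List[int] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == pair[0] and seq[i + 1] == pair[1]:
            out.append(new_id)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out
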