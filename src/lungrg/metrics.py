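"""Classification and caption-quality metrics.

Classification metrics are derived one-vs-rest from a 3x3 confusion matrix
(rows = true class, columns = predicted class, order Normal/SCLC/NSCLC):
per-class precision, recall, specificity = TN/(TN+FP) and F1, their
unweighted macro means, and overall accuracy.  Undefined ratios (zero
denominator) are reported as NaN, never silently as 0.  ROC-AUC is
one-vs-rest per class via scikit-learn.

Caption metrics for generated reports against single references:

* BLEU-n — corpus-level clipped n-gram precision with uniform weights 1/n
  and the standard brevity penalty.
* ROUGE-L — longest-common-subsequence F-measure with beta = 1.
* METEOR — exact-match unigram alignment F-mean (alpha = 0.9) with the
  fragmentation penalty gamma * (chunks/matches)^3, gamma = 0.5.
* CIDEr — tf-idf weighted n-gram cosine consensus, n = 1..4, uniform
  weights, scaled by 10 (plain CIDEr; idf from the reference corpus).

Caption tokenization is lowercase word/number tokens with punctuation
stripped — deliberately independent of the model's BPE vocabulary.
"""

from __future__ import annotations

import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CLASS_NAMES = ("Normal", "SCLC", "NSCLC")

_TOKEN_RE = re.compile(r"[a-z0-9çğıöşü]+", re.IGNORECASE | re.UNICODE)


def tokenize(text: str) -> List[str]:
    return [t.lower() for t in _TOKEN_RE.findall(text)]


# --------------------------------------------------------- classification

def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int],
                     n_classes: int = 3) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def classification_metrics(cm: np.ndarray,
                           class_names: Sequence[str] = CLASS_NAMES
                           ) -> Dict:
    """One-vs-rest metrics (percent, 2 decimals for reporting) from counts."""
    cm = np.asarray(cm)
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be nonnegative")
    total = cm.sum()
    per_class = {}
    for k, name in enumerate(class_names):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        f1 = _safe_div(2 * prec * rec, prec + rec) if prec == prec and \
            rec == rec else float("nan")
        per_class[name] = {"precision": prec, "recall": rec,
                           "specificity": spec, "f1": f1,
                           "support": int(cm[k].sum())}
    def macro(key):
        vals = [v[key] for v in per_class.values()]
        return float(np.mean(vals))
    out = {
        "per_class": per_class,
        "accuracy": _safe_div(np.trace(cm), total),
        "macro_precision": macro("precision"),
        "macro_recall": macro("recall"),
        "macro_specificity": macro("specificity"),
        "macro_f1": macro("f1"),
    }
    return out


def as_percent(x: float, decimals: int = 2) -> float:
    """Report-style rounding of a fraction to a percentage."""
    return float(np.round(100.0 * x, decimals))


def roc_auc(y_true: Sequence[int], probabilities: np.ndarray,
            class_names: Sequence[str] = CLASS_NAMES) -> Dict[str, float]:
    """One-vs-rest ROC-AUC per class; single-class truth -> NaN, flagged."""
    from sklearn.metrics import roc_auc_score
    y = np.asarray(y_true)
    p = np.asarray(probabilities, dtype=np.float64)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    out = {}
    for k, name in enumerate(class_names):
        pos = (y == k).astype(int)
        if pos.min() == pos.max():
            out[name] = float("nan")
        else:
            out[name] = float(roc_auc_score(pos, p[:, k]))
    return out


# ------------------------------------------------------------------ BLEU

def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1))


def bleu(candidates: Sequence[str], references: Sequence[str],
         max_n: int = 4) -> List[float]:
    """Corpus BLEU-1..max_n, uniform weights, standard brevity penalty."""
    if len(candidates) != len(references):
        raise ValueError("need one reference per candidate")
    cand_toks = [tokenize(c) for c in candidates]
    ref_toks = [tokenize(r) for r in references]
    c_len = sum(len(t) for t in cand_toks)
    r_len = sum(len(t) for t in ref_toks)
    bp = 1.0 if c_len > r_len else (math.exp(1 - r_len / c_len)
                                    if c_len > 0 else 0.0)
    precisions = []
    for n in range(1, max_n + 1):
        match = tot = 0
        for ct, rt in zip(cand_toks, ref_toks):
            cn, rn = _ngrams(ct, n), _ngrams(rt, n)
            match += sum(min(v, rn[g]) for g, v in cn.items())
            tot += max(len(ct) - n + 1, 0)
        precisions.append(_safe_div(match, tot) if tot else 0.0)
    scores = []
    for n in range(1, max_n + 1):
        ps = precisions[:n]
        if any(p == 0 or p != p for p in ps):
            scores.append(0.0)
        else:
            scores.append(bp * math.exp(sum(math.log(p) for p in ps) / n))
    return scores


# --------------------------------------------------------------- ROUGE-L

def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    dp = [0] * (len(b) + 1)
    for x in a:
        prev = 0
        for j, y in enumerate(b, 1):
            cur = dp[j]
            dp[j] = prev + 1 if x == y else max(dp[j], dp[j - 1])
            prev = cur
    return dp[-1]


def rouge_l(candidates: Sequence[str], references: Sequence[str],
            beta: float = 1.0) -> float:
    """Mean sentence-level LCS F-measure."""
    vals = []
    for c, r in zip(candidates, references):
        ct, rt = tokenize(c), tokenize(r)
        if not ct or not rt:
            vals.append(0.0)
            continue
        lcs = _lcs_len(ct, rt)
        p, rcl = lcs / len(ct), lcs / len(rt)
        if p + rcl == 0:
            vals.append(0.0)
        else:
            b2 = beta ** 2
            vals.append((1 + b2) * p * rcl / (rcl + b2 * p))
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------- METEOR

def _meteor_single(cand: List[str], ref: List[str], alpha: float,
                   gamma: float, exponent: float) -> float:
    if not cand or not ref:
        return 0.0
    # greedy in-order exact alignment: continue the previous match if the
    # next reference position carries the same token, else take the first
    # free occurrence
    free: Dict[str, List[int]] = defaultdict(list)
    for j, t in enumerate(ref):
        free[t].append(j)
    used = set()
    pairs: List[Tuple[int, int]] = []
    prev_j = -2
    for i, t in enumerate(cand):
        cands = [j for j in free.get(t, ()) if j not in used]
        if not cands:
            continue
        j = prev_j + 1 if prev_j + 1 in cands else cands[0]
        used.add(j)
        pairs.append((i, j))
        prev_j = j
    m = len(pairs)
    if m == 0:
        return 0.0
    p, r = m / len(cand), m / len(ref)
    fmean = p * r / (alpha * p + (1 - alpha) * r)
    chunks = 1
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if not (i1 == i0 + 1 and j1 == j0 + 1):
            chunks += 1
    penalty = gamma * (chunks / m) ** exponent
    return fmean * (1.0 - penalty)


def meteor(candidates: Sequence[str], references: Sequence[str],
           alpha: float = 0.9, gamma: float = 0.5,
           exponent: float = 3.0) -> float:
    vals = [_meteor_single(tokenize(c), tokenize(r), alpha, gamma, exponent)
            for c, r in zip(candidates, references)]
    return float(np.mean(vals)) if vals else 0.0


# ----------------------------------------------------------------- CIDEr

def cider(candidates: Sequence[str], references: Sequence[str],
          max_n: int = 4) -> float:
    """Plain CIDEr: mean over n of tf-idf n-gram cosine similarity, x10.
    Document frequencies come from the reference corpus."""
    cand_toks = [tokenize(c) for c in candidates]
    ref_toks = [tokenize(r) for r in references]
    n_docs = max(len(ref_toks), 1)
    sims = np.zeros(len(cand_toks))
    for n in range(1, max_n + 1):
        df: Counter = Counter()
        for rt in ref_toks:
            df.update(set(_ngrams(rt, n)))
        def tfidf(counts: Counter) -> Dict[Tuple, float]:
            total = sum(counts.values())
            if total == 0:
                return {}
            return {g: (c / total) * math.log(n_docs / max(df[g], 1))
                    for g, c in counts.items()}
        for i, (ct, rt) in enumerate(zip(cand_toks, ref_toks)):
            vc, vr = tfidf(_ngrams(ct, n)), tfidf(_ngrams(rt, n))
            dot = sum(vc[g] * vr.get(g, 0.0) for g in vc)
            nc = math.sqrt(sum(v * v for v in vc.values()))
            nr = math.sqrt(sum(v * v for v in vr.values()))
            if nc > 0 and nr > 0:
                sims[i] += dot / (nc * nr)
    sims *= 10.0 / max_n
    return float(sims.mean()) if len(sims) else 0.0


# ---------------------------------------------------------------- bundles

@dataclass
class CaptionScores:
    bleu: List[float]
    rouge_l: float
    meteor: float
    cider: float


def caption_metrics(candidates: Sequence[str], references: Sequence[str]
                    ) -> CaptionScores:
    """All caption metrics; empty candidates score 0 with a warning."""
    if len(candidates) != len(references):
        raise ValueError("need one reference per candidate")
    if any(not c.strip() for c in candidates):
        import warnings
        warnings.warn("empty candidate text; scores default to 0")
    return CaptionScores(bleu=bleu(candidates, references),
                         rouge_l=rouge_l(candidates, references),
                         meteor=meteor(candidates, references),
                         cider=cider(candidates, references))


def confidence_analysis(predictions, truths: Sequence[int]) -> Dict:
    """Max-softmax confidence per case, split by correctness.

    ``predictions``: sequence of objects with ``predicted_class`` and
    ``max_confidence`` (see pooling.ClassPrediction).
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    records = [{"max_confidence": float(p.max_confidence),
                "correct": int(p.predicted_class) == int(t)}
               for p, t in zip(predictions, truths)]
    def group(flag):
        vals = [r["max_confidence"] for r in records if r["correct"] == flag]
        if not vals:
            return {"n": 0, "mean": float("nan"), "min": float("nan"),
                    "max": float("nan")}
        return {"n": len(vals), "mean": float(np.mean(vals)),
                "min": float(np.min(vals)), "max": float(np.max(vals))}
    return {"records": records, "correct": group(True),
            "incorrect": group(False)}


def metrics_table(metrics: Dict, scenario: str = "") -> pd.DataFrame:
    """Per-class + overall rows in the published report layout (percent)."""
    rows = []
    for name, d in metrics["per_class"].items():
        for key in ("precision", "recall", "specificity", "f1"):
            rows.append({"Class": name, "Metric": key.capitalize(),
                         "Scenario": scenario, "Value (%)":
                         as_percent(d[key])})
    for key in ("accuracy", "macro_precision", "macro_recall",
                "macro_specificity", "macro_f1"):
        rows.append({"Class": "Overall", "Metric": key, "Scenario": scenario,
                     "Value (%)": as_percent(metrics[key])})
    return pd.DataFrame(rows)
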