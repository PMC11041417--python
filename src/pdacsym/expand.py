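"""Offline lexicon-expansion helper.

Proposes candidate trigger terms — including misspellings — by training
distributional word embeddings on a note corpus and ranking vocabulary
items by cosine similarity to a set of seed terms.  Embeddings are
window co-occurrence counts reweighted by positive pointwise mutual
information (PPMI) and factored with a truncated SVD; on clinical text
this captures the same "words used in the same contexts" signal as
shallow predictive embeddings while staying deterministic.

Candidates are proposals for human review only: the extraction path
never consults this module, so extraction stays deterministic and
auditable regardless of the corpus used here.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import svds

#: Minimum corpus size (tokens) for a usable co-occurrence estimate.
MIN_CORPUS_TOKENS = 50
MIN_VOCAB = 10


class CorpusTooSmallError(ValueError):
    pass


def _as_token_sequences(corpus: Iterable) -> list[list[str]]:
    out = []
    for item in corpus:
        if isinstance(item, str):
            out.append(item.lower().split())
        else:
            out.append([str(t).lower() for t in item])
    return out


def train_embeddings(corpus: Iterable[Sequence[str] | str],
                     window: int = 2, dim: int = 50,
                     min_count: int = 1,
                     ) -> tuple[list[str], np.ndarray]:
    """PPMI-SVD embeddings over a corpus of token sequences.

    Returns ``(vocabulary, vectors)`` with one row per vocabulary word.
    """
    sents = _as_token_sequences(corpus)
    n_tokens = sum(len(s) for s in sents)
    counts: dict[str, int] = {}
    for s in sents:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if n_tokens < MIN_CORPUS_TOKENS or len(vocab) < MIN_VOCAB:
        raise CorpusTooSmallError(
            f"corpus too small to train embeddings ({n_tokens} tokens, "
            f"{len(vocab)} vocabulary items); need at least "
            f"{MIN_CORPUS_TOKENS} tokens and {MIN_VOCAB} distinct words")
    index = {w: i for i, w in enumerate(vocab)}
    rows: list[int] = []
    cols: list[int] = []
    for s in sents:
        ids = [index[t] for t in s if t in index]
        for i, wi in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    rows.append(wi)
                    cols.append(ids[j])
    cooc = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(vocab), len(vocab))).tocsr()
    total = cooc.sum()
    row_sums = np.asarray(cooc.sum(axis=1)).ravel()
    col_sums = np.asarray(cooc.sum(axis=0)).ravel()
    cooc = cooc.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(cooc.data * total
                     / (row_sums[cooc.row] * col_sums[cooc.col]))
    ppmi_data = np.maximum(pmi, 0.0)
    ppmi = sparse.coo_matrix((ppmi_data, (cooc.row, cooc.col)),
                             shape=(len(vocab), len(vocab))).tocsr()
    k = min(dim, len(vocab) - 2)
    if k < 1:
        raise CorpusTooSmallError("vocabulary too small for SVD")
    u, s, _ = svds(ppmi, k=k, v0=np.ones(len(vocab)))
    order = np.argsort(s)[::-1]
    vectors = u[:, order] * np.sqrt(s[order])
    return vocab, vectors


def expand_candidate_terms(corpus: Iterable[Sequence[str] | str],
                           seeds: Iterable[str], k: int = 10,
                           window: int = 2, dim: int = 50,
                           ) -> list[tuple[str, float]]:
    """Up to ``k`` candidate terms nearest (cosine) to the seed terms.

    Seeds themselves are never returned; scores are non-increasing down
    the ranking.  Seeds absent from the corpus vocabulary yield an empty
    list with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seeds = {s.lower() for s in seeds}
    if not seeds:
        raise ValueError("at least one seed term is required")
    vocab, vectors = train_embeddings(corpus, window=window, dim=dim)
    index = {w: i for i, w in enumerate(vocab)}
    present = [s for s in seeds if s in index]
    if not present:
        warnings.warn("no seed term occurs in the corpus vocabulary; "
                      "no candidates proposed", stacklevel=2)
        return []
    norms = np.linalg.norm(vectors, axis=1)
    norms[norms == 0] = 1.0
    unit = vectors / norms[:, None]
    seed_vec = unit[[index[s] for s in present]].mean(axis=0)
    nrm = np.linalg.norm(seed_vec)
    if nrm == 0:
        return []
    seed_vec /= nrm
    sims = unit @ seed_vec
    ranked = sorted(
        ((w, float(sims[i])) for w, i in index.items() if w not in seeds),
        key=lambda t: (-t[1], t[0]))
    return ranked[:k]
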