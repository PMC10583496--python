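"""Brute-force reference implementations used only to cross-check the
package's feature computations.  Written independently of the library code:
plain loops, collections.Counter, math module."""

import math
from collections import Counter


def profile_counts(word_surfaces):
    c = Counter(word_surfaces)
    n = sum(c.values())
    v = len(c)
    v1 = len([w for w, k in c.items() if k == 1])
    return n, v, v1


def ttr(word_surfaces):
    n, v, _ = profile_counts(word_surfaces)
    return v / n


def honore(n, v, v1):
    if v1 == v:
        return math.nan
    return 100.0 * math.log(n) / (1.0 - v1 / v)


def brunet(n, v):
    return math.pow(n, math.pow(v, -0.165))


def mean_log_freq(word_surfaces, table, floor):
    total = 0.0
    for w in word_surfaces:
        total += math.log10(table[w] if w in table else floor)
    return total / len(word_surfaces)


def proportions(word_surfaces, tags, fillers, empty_words, stop_words):
    n = len(word_surfaces)
    out = {}
    out["fillers"] = len([w for w in word_surfaces if w in fillers])
    out["empty_words"] = len([w for w in word_surfaces if w in empty_words])
    out["definite_articles"] = word_surfaces.count("the")
    out["indefinite_articles"] = len([w for w in word_surfaces if w in ("a", "an")])
    out["pronouns"] = len([t for t in tags if t in ("PRP", "PRP$", "WP", "WP$")])
    out["nouns"] = len([t for t in tags if t[:2] == "NN"])
    out["verbs"] = len([t for t in tags if t[:2] == "VB"])
    out["determiners"] = len([t for t in tags if t in ("DT", "PDT", "WDT")])
    out["content_words"] = len([w for w in word_surfaces if w not in stop_words])
    return {k: 100.0 * c / n for k, c in out.items()}


def rates(all_token_count, filler_count, duration):
    return all_token_count / duration, filler_count / duration
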