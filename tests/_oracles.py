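"""Brute-force reference implementations used only to cross-check the
vectorised pipeline on small datasets.

Each function evaluates one query variant at a time with plain loops and
Counter arithmetic, independently of the pandas group-by logic in the
package.
"""

from collections import Counter

from metadomain.evaluation import ContingencyTable


def _assign(labels, rule):
    c = Counter(labels)
    p, b = c["pathogenic"], c["benign"]
    if p + b == 0:
        return "empty"
    if p + b == 1:
        return "unique"
    if b == 0:
        return "pathogenic"
    if p == 0:
        return "benign"
    if rule == "no_conflict" or p == b:
        return "conflicting"
    return "pathogenic" if p > b else "benign"


def oracle_standard(dataset, direction):
    """Case-by-case same-protein co-localisation contingency."""
    tp = fp = fn = tn = unique = 0
    records = dataset.to_dict(orient="records")
    for q in records:
        others = [
            r for r in records
            if r["protein_id"] == q["protein_id"]
            and r["residue_index"] == q["residue_index"]
            and (r["ref_aa"], r["alt_aa"]) != (q["ref_aa"], q["alt_aa"])
        ]
        positive = bool(others) and all(r["label"] == direction for r in others)
        if not others:
            unique += 1
        if positive and q["label"] == direction:
            tp += 1
        elif positive:
            fp += 1
        elif q["label"] == direction:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp, fp, fn, tn, n_unique=unique)


def oracle_meta(dataset, mapping, rule, direction):
    """Case-by-case meta-position contingency (query included in counts)."""
    meta_of = {}
    for r in mapping.to_dict(orient="records"):
        meta_of.setdefault((r["protein_id"], r["residue_index"]), []).append(
            (r["family_id"], r["column_label"]))
    records = dataset.to_dict(orient="records")
    tp = fp = fn = tn = unique = 0
    for q in records:
        metas = meta_of.get((q["protein_id"], q["residue_index"]), [])
        assignments = []
        for meta in metas:
            labels = [
                r["label"] for r in records
                if meta in meta_of.get((r["protein_id"], r["residue_index"]), [])
            ]
            assignments.append(_assign(labels, rule))
        positive = any(a == direction for a in assignments)
        if metas and all(a == "unique" for a in assignments):
            unique += 1
        if positive and q["label"] == direction:
            tp += 1
        elif positive:
            fp += 1
        elif q["label"] == direction:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp, fp, fn, tn, n_unique=unique)
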