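"""Independently coded brute-force reference for pseudo-label assignment.

Explicit Python loops and ``math`` scalars only — deliberately shares no code
with the package implementation so it can serve as an oracle.
"""

import math


def brute_force_assign(features, labels, centers, seen, alpha, ns, mode):
    """Reference pseudo-label assignment for one batch.

    ``features`` is a list of rows, ``labels`` a list of ints, ``centers`` a
    list of per-class center rows (mutated copy returned), ``seen`` per-class
    update counts.  Returns (pseudo_labels, new_centers, new_seen).
    """
    n_classes = len(ns)
    offsets = []
    acc = 0
    for n in ns:
        offsets.append(acc)
        acc += n
    dim = len(features[0])
    centers = [list(row) for row in centers]
    seen = list(seen)
    pseudo = [None] * len(labels)

    for c in range(n_classes):
        members = [i for i, lab in enumerate(labels) if lab == c]
        if not members:
            continue
        mean = [
            sum(features[i][d] for i in members) / len(members) for d in range(dim)
        ]
        if seen[c] == 0:
            centers[c] = mean
        else:
            centers[c] = [
                alpha * mean[d] + (1.0 - alpha) * centers[c][d] for d in range(dim)
            ]
        seen[c] += 1

        dists = [
            math.sqrt(sum((features[i][d] - centers[c][d]) ** 2 for d in range(dim)))
            for i in members
        ]
        k = ns[c]
        if mode == "equal_width":
            dmax = max(dists)
            if dmax - min(dists) <= 1e-9 * dmax:
                subs = [0] * len(members)
            else:
                width = dmax / k
                subs = [min(int(math.floor(d / width)), k - 1) for d in dists]
        elif mode == "equal_rank":
            order = sorted(range(len(members)), key=lambda j: (dists[j], j))
            count = len(members)
            base, rem = divmod(count, k)
            subs = [0] * count
            pos = 0
            for block in range(k):
                size = base + (1 if block < rem else 0)
                for _ in range(size):
                    if pos < count:
                        subs[order[pos]] = block
                        pos += 1
        else:
            raise ValueError(mode)
        for i, sub in zip(members, subs):
            pseudo[i] = offsets[c] + sub

    return pseudo, centers, seen


def brute_force_confusion(true_labels, predictions, n_classes):
    """Hand-counted confusion matrix, precision, recall, F1."""
    conf = [[0] * n_classes for _ in range(n_classes)]
    for t, p in zip(true_labels, predictions):
        conf[t][p] += 1
    precision, recall, f1 = [], [], []
    for c in range(n_classes):
        tp = conf[c][c]
        fp = sum(conf[r][c] for r in range(n_classes)) - tp
        fn = sum(conf[c]) - tp
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        precision.append(prec)
        recall.append(rec)
        f1.append(2 * prec * rec / (prec + rec) if (prec + rec) else 0.0)
    return conf, precision, recall, f1
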