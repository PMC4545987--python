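"""Text item-person (Wright) maps.

Two aligned panels share one vertical logit axis: the left panel shows the
person-measure distribution ('#' per a configurable person count), the
right panel the item step locations.  Polytomous items are labelled
``item.k`` where ``k`` is the upper category of the step (a 5-category item
renders four labels ``x.2``..``x.5``); dichotomous items, having a single
threshold, are labelled by their bare id.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np


def wright_map(result, bin_width: Optional[float] = None,
               persons_per_hash: Optional[int] = None,
               max_hashes: int = 40) -> str:
    cfg = result.config
    if bin_width is None:
        bin_width = cfg.wright_bin
    if persons_per_hash is None:
        persons_per_hash = cfg.wright_persons_per_hash
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    spec = result.model.spec
    theta = result.theta_all.dropna().to_numpy()
    labels = []   # (logit, text)
    for i in result.items:
        tau = np.asarray(result.taus[spec[i].scale_group])
        d = float(result.delta.loc[i])
        if tau.shape[0] == 1:
            labels.append((d + float(tau[0]), i))
        else:
            for t in range(tau.shape[0]):
                labels.append((d + float(tau[t]), f"{i}.{t + 2}"))

    lo = min(float(theta.min()), min(l for l, _ in labels))
    hi = max(float(theta.max()), max(l for l, _ in labels))
    row_lo = math.floor(lo / bin_width)
    row_hi = math.ceil(hi / bin_width)

    def row_of(x: float) -> int:
        return int(np.clip(round(x / bin_width), row_lo, row_hi))

    person_rows = {}
    for t in theta:
        person_rows[row_of(t)] = person_rows.get(row_of(t), 0) + 1
    label_rows = {}
    for x, text in labels:
        label_rows.setdefault(row_of(x), []).append((x, text))

    lines: List[str] = []
    lines.append(f"{'persons':>{8 + max_hashes}} | items")
    for r in range(row_hi, row_lo - 1, -1):
        center = r * bin_width
        n = person_rows.get(r, 0)
        hashes = "#" * min(math.ceil(n / persons_per_hash), max_hashes)
        right = "  ".join(t for _, t in sorted(label_rows.get(r, []),
                                               key=lambda e: (e[0], e[1])))
        lines.append(f"{center:7.2f} {hashes:>{max_hashes}} | {right}".rstrip())
    lines.append(
        f"(each '#' = {persons_per_hash} person(s); bin = {bin_width:g} logits)"
    )
    return "\n".join(lines)
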