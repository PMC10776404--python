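"""Deliberately naive reference implementations used only to check the package.

These enumerate every possibility explicitly (template strings, per-position
comparison, exhaustive loops) and share no code with the library.
"""

from __future__ import annotations


def _templates(scheme):
    """All (template, n_indels, order) adapter templates with '?' at UMI slots.

    Decomposition order mirrors the documented tie-break: no indel first,
    then read-start deletion/insertion, then second-UMI deletion/insertion.
    """
    u1 = "?" * scheme.umi1_len
    u2 = "?" * scheme.umi2_len
    out = []
    order = 0
    for (du1, du2) in [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]:
        for sbc in scheme.sbc_whitelist:
            for entry in scheme.abbc_whitelist:
                t = (
                    "?" * (scheme.umi1_len + du1)
                    + sbc[: scheme.sbc1_len]
                    + "?" * (scheme.umi2_len + du2)
                    + sbc[scheme.sbc1_len :]
                    + scheme.constant
                    + entry.barcode
                )
                out.append((t, int(du1 != 0) + int(du2 != 0), order, du1, du2, sbc, entry.barcode))
        order += 1
    return out


def oracle_match(seq, scheme, max_errors=2, min_overlap=29):
    """Exhaustive anchored decomposition search.

    Returns (errors, shift_start, shift_umi2, sbc, abbc, adapter_end) of the
    best candidate, or None.  Ambiguity rule: if at the winning decomposition
    two different sample barcodes (or antibody barcodes) reach the same
    minimal error count via nonzero barcode edits, the decomposition is
    discarded.
    """
    by_order: dict[int, list] = {}
    for t, n_ind, order, du1, du2, sbc, abbc in _templates(scheme):
        n_cmp = min(len(seq), len(t))
        overlap = n_cmp - du1 - du2
        if overlap < min_overlap:
            continue
        const_start = len(t) - len(scheme.constant) - scheme.abbc_len
        if n_cmp < const_start + len(scheme.constant):
            continue  # constant linker must be fully covered
        mm = 0
        for i in range(n_cmp):
            if t[i] != "?" and seq[i] != t[i]:
                mm += 1
        errors = mm + n_ind
        if errors <= max_errors:
            by_order.setdefault(order, []).append((errors, du1, du2, sbc, abbc, len(t)))

    candidates = []
    for order, cands in by_order.items():
        best_err = min(c[0] for c in cands)
        winners = [c for c in cands if c[0] == best_err]
        sbcs = {c[3] for c in winners}
        abbcs = {c[4] for c in winners}
        if len(winners) > 1 and (len(sbcs) > 1 or len(abbcs) > 1):
            continue  # ambiguous barcode rescue at this decomposition -> rejected
        candidates.append((winners[0][0], order) + winners[0][1:])
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[5], c[6]))
    errors, _, du1, du2, sbc, abbc, end = candidates[0]
    return errors, du1, du2, sbc, abbc, end


def oracle_classify(seq, scheme, max_errors=2, min_overlap=29):
    """Class + barcodes per the documented seven-tier ladder, naively."""
    m = oracle_match(seq, scheme, max_errors, min_overlap)
    if m is not None:
        errors, du1, du2, sbc, abbc, _ = m
        n_ind = int(du1 != 0) + int(du2 != 0)
        mm = errors - n_ind
        if errors == 0:
            return 1, sbc, abbc
        if du1 != 0 and du2 == 0 and mm == 0:
            return 2, sbc, abbc
        if n_ind == 0:
            return 3, sbc, abbc
        return 4, sbc, abbc
    off = scheme.constant_offset
    const = scheme.constant
    for delta in (-1, 1):
        if seq[off + delta : off + delta + len(const)] == const:
            return 5, "", ""
    window = seq[off : off + len(const)]
    if len(window) == len(const):
        mm = sum(1 for a, b in zip(window, const) if a != b)
        if mm == 1:
            return 6, "", ""
        if mm == 0:
            return 7, "", ""
    return 0, "", ""


def naive_motif_count(seq: str, motif: str) -> int:
    return sum(1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif)
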