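"""Independent brute-force oracles the tests compare the package against.

Everything here is written from the definitions alone, without calling the
implementation under test: an all-windows enumerator for locus detection, a
truth-table tier classifier, hand-built glucan typing tables, and a naive
two-strand substring scanner.
"""

from __future__ import annotations

DEGRADATIVE_PREFIXES = ("GH", "PL", "CE")
MARKER_ROLES = {"SUSC", "SUSD", "TBDT_OTHER", "SULFATASE"}
TRANSPORTER_ROLES = {"SUSC", "SUSD", "TBDT_OTHER"}


def _is_degradative_label(fam: str) -> bool:
    return fam[:2] in DEGRADATIVE_PREFIXES and not fam.startswith("CB")


def _is_marker_spec(families, roles) -> bool:
    return bool(set(roles) & MARKER_ROLES) or any(
        _is_degradative_label(f) for f in families
    )


def brute_force_loci(marker_flags: list[bool], window_length: int, min_markers: int):
    """Enumerate every window, collect covered genes of hit windows, split
    into maximal consecutive runs, trim each run to marker boundaries.
    Returns a list of (first_index, last_index) spans."""
    n = len(marker_flags)
    if n == 0:
        return []
    if n <= window_length:
        windows = [range(0, n)]
    else:
        windows = [range(s, s + window_length) for s in range(n - window_length + 1)]
    covered: set[int] = set()
    for w in windows:
        if sum(marker_flags[i] for i in w) >= min_markers:
            covered.update(w)
    spans = []
    for i in sorted(covered):
        if spans and i == spans[-1][1] + 1:
            spans[-1][1] = i
        else:
            spans.append([i, i])
    trimmed = []
    for lo, hi in spans:
        while lo <= hi and not marker_flags[lo]:
            lo += 1
        while hi >= lo and not marker_flags[hi]:
            hi -= 1
        if lo <= hi:
            trimmed.append((lo, hi))
    return trimmed


def tier_oracle(gene_specs, same_strand: bool = True) -> str:
    """Tier from the three definitions: a susCD tandem plus >= 1 degradative
    CAZyme is a PUL; >= 1 transporter gene plus >= 1 degradative CAZyme is
    PUL-like; >= 3 degradative CAZyme domains is CAZyme-rich; else
    unclassified.  ``gene_specs`` are (families, roles, strand) triples in
    contig order."""
    deg = sum(
        1 for fams, _, _ in gene_specs for f in fams if _is_degradative_label(f)
    )
    tandem = False
    for (f1, r1, s1), (f2, r2, s2) in zip(gene_specs, gene_specs[1:]):
        pair = ("SUSC" in r1 and "SUSD" in r2) or ("SUSD" in r1 and "SUSC" in r2)
        if pair and (not same_strand or s1 == s2):
            tandem = True
    transporters = sum(1 for _, roles, _ in gene_specs if set(roles) & TRANSPORTER_ROLES)
    if tandem and deg >= 1:
        return "PUL"
    if transporters >= 1 and deg >= 1:
        return "PUL_LIKE"
    if deg >= 3:
        return "CAZYME_RICH"
    return "UNCLASSIFIED"


def alpha_glucan_truth_table() -> dict[frozenset, str]:
    """Hand-built table over the 2^5 subsets of {GH13,GH31,GH57,GH65,GH77}."""
    from itertools import combinations

    alphabet = ("GH13", "GH31", "GH57", "GH65", "GH77")
    labelled = {
        frozenset({"GH13"}): "I",
        frozenset({"GH13", "GH65"}): "II",
        frozenset({"GH13", "GH65", "GH31"}): "II",
        frozenset({"GH13", "GH77", "GH57"}): "III",
        frozenset({"GH13", "GH31"}): "IV",
    }
    table = {}
    for r in range(len(alphabet) + 1):
        for combo in combinations(alphabet, r):
            F = frozenset(combo)
            table[F] = labelled.get(F, "none")
    return table


def beta_glucan_truth_table(variant1_min: int = 3) -> dict[frozenset, str]:
    """Hand-built table over the 2^6 subsets of the laminarin-PUL alphabet,
    with precedence GH16-only > variant-2 > variant-1."""
    from itertools import combinations

    alphabet = ("GH3", "GH16", "GH17", "GH30", "GH149", "GH158")
    hallmarks = {"GH149", "GH17", "GH16", "GH158", "GH30"}
    variant2_sets = [
        frozenset({"GH3", "GH16"}),
        frozenset({"GH3", "GH17"}),
        frozenset({"GH3", "GH16", "GH17"}),
    ]
    table = {}
    for r in range(len(alphabet) + 1):
        for combo in combinations(alphabet, r):
            F = frozenset(combo)
            if F == frozenset({"GH16"}):
                table[F] = "GH16-only"
            elif F in variant2_sets:
                table[F] = "variant-2"
            elif len(F & hallmarks) >= variant1_min:
                table[F] = "variant-1"
            else:
                table[F] = "none"
    return table


def substring_scan(asv: str, subject: str) -> bool:
    """Naive two-strand scan: does the ASV occur mismatch-free in the
    subject (or its reverse complement), with no N anywhere in the match?"""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(asv))
    for query in (asv, rc):
        m = len(query)
        for start in range(len(subject) - m + 1):
            window = subject[start : start + m]
            if all(a == b and a != "N" for a, b in zip(query, window)):
                return True
    return False
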