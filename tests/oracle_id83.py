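"""Independent brute-force ID83 classifier used as a test oracle.

Works directly on the raw contig string with linear scans and regex
matching, sharing no code with the package's classifier.  Input records
are assumed left-aligned (the planted fixtures guarantee it).
"""

import re

_PYR = {"A": "T", "G": "C", "C": "C", "T": "T"}


def _lcp(x: str, y: str) -> int:
    n = 0
    for a, b in zip(x, y):
        if a != b:
            break
        n += 1
    return n


def oracle_id83(seq: str, pos: int, ref: str, alt: str) -> str:
    """Channel label for an indel at 1-based ``pos`` on contig ``seq``."""
    i = pos - 1
    if alt == "-":  # deletion
        L = len(ref)
        assert seq[i : i + L] == ref, "oracle: reference mismatch"
        left, right = seq[:i], seq[i + L :]
        if L == 1:
            j, k = i, i
            while j > 0 and seq[j - 1] == ref:
                j -= 1
            while k + 1 < len(seq) and seq[k + 1] == ref:
                k += 1
            run = k - j + 1
            return f"1:Del:{_PYR[ref]}:{min(run, 6) - 1}"
        copies = 1 + len(re.match(f"(?:{ref})*", right).group(0)) // L
        size = min(L, 5)
        if copies >= 2:
            return f"{size}:Del:R:{min(copies, 6) - 1}"
        mh = max(min(_lcp(ref, right), L - 1),
                 min(_lcp(ref[::-1], left[::-1]), L - 1))
        if mh >= 1:
            return f"{size}:Del:M:{min(mh, 5)}"
        return f"{size}:Del:R:0"

    # insertion anchored at the base 5' of the inserted sequence
    L = len(alt)
    left, right = seq[: i + 1], seq[i + 1 :]
    if L == 1:
        lrun = len(left) - len(left.rstrip(alt))
        rrun = len(right) - len(right.lstrip(alt))
        return f"1:Ins:{_PYR[alt]}:{min(max(lrun, rrun), 5)}"
    copies = len(re.match(f"(?:{alt})*", right).group(0)) // L
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"
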