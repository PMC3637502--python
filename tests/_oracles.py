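"""Independent brute-force oracles used to cross-check the fast implementations.

Each oracle re-derives its answer from first principles (exhaustive
enumeration, naive loops, literal lookup tables) and deliberately shares no
code with the module it checks.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def hamming_scan_oracle(read_seq: str, mature_dna: str, max_mm: int):
    """All (start0, strand, mismatches) full-length placements by direct enumeration."""
    out = []
    L = len(mature_dna)
    for strand, query in (("+", mature_dna), ("-", revcomp(mature_dna))):
        for off in range(len(read_seq) - L + 1):
            window = read_seq[off : off + L]
            if "N" in window:
                continue
            mm = sum(1 for a, b in zip(window, query) if a != b)
            if mm <= max_mm:
                out.append((off, strand, mm))
    return sorted(out)


def ssr_oracle(seq: str, thresholds: dict[int, int]):
    """Maximal perfect tandem runs via the period-continuation formulation.

    For each period k, positions p with seq[p] == seq[p+k] form runs; a
    maximal interval of consecutive such positions [a, b) spans the repeat
    region [a, b+k).  The record starts at a with motif seq[a:a+k] and
    counts only whole motif copies.
    """
    found = []
    n = len(seq)
    for k in thresholds:
        cont = [
            p
            for p in range(n - k)
            if seq[p] == seq[p + k] and seq[p] != "N" and seq[p + k] != "N"
        ]
        runs = []
        for p in cont:
            if runs and p == runs[-1][1]:
                runs[-1] = (runs[-1][0], p + 1)
            else:
                runs.append((p, p + 1))
        for a, b in runs:
            span = b + k - a
            reps = span // k
            motif = seq[a : a + k]
            if "N" in motif:
                continue
            primitive = all(
                not (k % d == 0 and motif == motif[:d] * (k // d)) for d in range(1, k)
            )
            if primitive and reps >= thresholds[k]:
                found.append((a + 1, a + reps * k, motif, reps))
    return sorted(found)


_STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq: str) -> int:
    """Longest ATG..stop ORF (codons incl. ATG) over six frames, by direct walk."""
    best = 0
    for s in (seq, revcomp(seq)):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            for start, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                length = 0
                terminated = False
                for c in codons[start:]:
                    if c in _STOPS:
                        terminated = True
                        break
                    length += 1
                if terminated:
                    best = max(best, length)
    return best


# literal RNA pairing costs: mature base (rows) x target base (cols)
_PAIR_COST = {
    ("A", "U"): 0.0, ("U", "A"): 0.0, ("G", "C"): 0.0, ("C", "G"): 0.0,
    ("G", "U"): 0.5, ("U", "G"): 0.5,
}


def score_site_oracle(mature_rna: str, site_dna: str) -> float:
    site_rna = site_dna.replace("T", "U")
    total = 0.0
    for i, mb in enumerate(mature_rna):
        tb = site_rna[len(site_rna) - 1 - i]
        total += _PAIR_COST.get((mb, tb), 1.0)
    return total


def venn_oracle(sets: dict[str, set[str]]):
    """Region counts via per-id membership bitmasks."""
    labels = sorted(sets)
    counts: dict[int, int] = {}
    universe = set()
    for s in sets.values():
        universe |= set(s)
    for uid in universe:
        mask = sum(1 << i for i, lab in enumerate(labels) if uid in sets[lab])
        counts[mask] = counts.get(mask, 0) + 1
    return {
        frozenset(lab for i, lab in enumerate(labels) if mask >> i & 1): n
        for mask, n in counts.items()
    }


def end_trim_oracle(seq: str, adapters: list[str], rate: float, min_overlap: int = 8):
    """(left_trim, right_trim) by exhaustive enumeration of all end overlaps."""
    left = 0
    for ad in adapters:
        for length in range(min_overlap, min(len(seq), len(ad)) + 1):
            mm = sum(1 for a, b in zip(ad[-length:], seq[:length]) if a != b)
            if mm <= int(rate * length):
                left = max(left, length)
    rest = seq[left:]
    right = 0
    for ad in adapters:
        for length in range(min_overlap, min(len(rest), len(ad)) + 1):
            mm = sum(1 for a, b in zip(ad[:length], rest[-length:]) if a != b)
            if mm <= int(rate * length):
                right = max(right, length)
    return left, right
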