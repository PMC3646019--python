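from itertools import permutations

import pytest

from coremk.sequence_io import GeneAlignment, get_code


def make_alignment(gene_id="g", **rows):
    """Build a GeneAlignment from keyword label=sequence pairs."""
    return GeneAlignment.from_dict(gene_id, rows)


@pytest.fixture
def code():
    return get_code(11)


def oracle_pathway_counts(codon_a, codon_b, code):
    """Independent shortest-stop-free-pathway enumeration.

    Enumerates every ordering of the differing positions explicitly,
    collects the (non-syn, syn) step classification for orderings whose
    intermediate codons are not stops, and averages; falls back to all
    orderings when every one passes through a stop.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)

    def classify(order, forbid_stops):
        states = [codon_a]
        for pos in order:
            prev = states[-1]
            nxt = prev[:pos] + codon_b[pos] + prev[pos + 1 :]
            states.append(nxt)
        if forbid_stops and any(code.is_stop(s) for s in states[1:-1]):
            return None
        n = s = 0
        for a, b in zip(states, states[1:]):
            if code.translate_codon(a) == code.translate_codon(b):
                s += 1
            else:
                n += 1
        return (n, s)

    results = [classify(o, True) for o in permutations(diff)]
    results = [r for r in results if r is not None]
    if not results:
        results = [classify(o, False) for o in permutations(diff)]
    n = sum(r[0] for r in results) / len(results)
    s = sum(r[1] for r in results) / len(results)
    return (n, s)


def oracle_count_single_codon(ingroup_codons, outgroup_codons, code):
    """Brute-force MK classification of one codon column.

    Re-implements the bookkeeping rules independently: skip dirty codons,
    polymorphism connects each distinct minor codon to the majority codon,
    divergence compares the monomorphic ingroup codon to the outgroup
    majority-rule consensus.
    """
    acgt = set("ACGT")
    if any(set(c) - acgt for c in list(ingroup_codons) + list(outgroup_codons)):
        return None  # skipped column
    pn = ps = dn = ds = 0.0
    distinct = sorted(set(ingroup_codons))
    if len(distinct) > 1:
        freq = {c: ingroup_codons.count(c) for c in distinct}
        top = max(freq.values())
        major = sorted(c for c in freq if freq[c] == top)[0]
        for c in distinct:
            if c != major:
                n, s = oracle_pathway_counts(major, c, code)
                pn += n
                ps += s
    else:
        freq = {c: outgroup_codons.count(c) for c in set(outgroup_codons)}
        top = max(freq.values())
        winners = sorted(c for c in freq if freq[c] == top)
        if len(winners) != 1:
            return (0.0, 0.0, 0.0, 0.0)
        rep = winners[0]
        if rep != distinct[0]:
            n, s = oracle_pathway_counts(distinct[0], rep, code)
            dn += n
            ds += s
    return (pn, ps, dn, ds)
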