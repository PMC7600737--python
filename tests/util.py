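"""Small shared helpers for building variants in tests."""

from poolsweep.variant_io import PooledVariant


def pv(pos, counts, contig="c1", qual=50.0, ref="A", alt="C"):
    return PooledVariant(
        contig=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        counts=tuple(tuple(c) for c in counts),
    )


def random_counts(rng, n_pops, depth=12):
    out = []
    for _ in range(n_pops):
        d = int(rng.poisson(depth)) + 1
        a = int(rng.integers(0, d + 1))
        out.append((d - a, a))
    return tuple(out)
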