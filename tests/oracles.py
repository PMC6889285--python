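"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: the Poisson tail
is summed term by term; NMD biotypes come from Biopython translation of
the rebuilt mRNA plus a direct junction-distance computation.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

from exon_unmask.intervals import GenomicInterval


def poisson_tail_series(lam: float, k: int, terms: int = 300) -> float:
    """P(X >= k) by direct summation of the upper-tail pmf series."""
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    parts = []
    for j in range(k, k + terms):
        parts.append(term)
        term *= lam / (j + 1)
    return math.fsum(parts)


def build_random_host(rng, n_exons: int = 5):
    """Random plus-strand multi-exon coding transcript with its mRNA.

    Returns (transcript, mrna, cds_start_offset); the CDS is ATG + random
    non-stop codons + TAA, placed after a 20-nt 5' UTR.
    """
    from conftest import make_tx
    from exon_unmask.nmd import genomic_position

    exons = []
    pos = 1
    for _ in range(n_exons):
        length = int(rng.integers(60, 200))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(100, 400))
    tx = make_tx(exons, cds=None)
    spliced = tx.spliced_length()
    utr5 = 20
    cds_len = (spliced - 40) // 3 * 3
    g1 = genomic_position(tx, utr5 + 1)
    g2 = genomic_position(tx, utr5 + cds_len)
    tx = make_tx(exons, cds=(min(g1, g2), max(g1, g2)))
    non_stop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]
    codons = [non_stop[int(rng.integers(len(non_stop)))]
              for _ in range(cds_len // 3 - 2)]
    bases = "ACGT"
    rand = lambda n: "".join(bases[int(rng.integers(4))] for _ in range(n))
    mrna = rand(utr5) + "ATG" + "".join(codons) + "TAA" + rand(spliced - utr5 - cds_len)
    return tx, mrna, utr5 + 1


def translation_biotype(host, mrna: str, cds_start: int,
                        exon_iv: GenomicInterval, exon_seq: str,
                        ptc: int = 50) -> str:
    """Oracle biotype for a cassette inclusion: splice the exon in,
    translate with Biopython to find the first stop, and apply the
    junction-distance rule directly."""
    exons = sorted(list(host.exons) + [exon_iv], key=lambda e: e.start)
    lens = [e.end - e.start + 1 for e in exons]
    idx = exons.index(exon_iv)
    u = sum(lens[:idx])
    new_mrna = mrna[:u] + exon_seq + mrna[u:]
    junctions = np.cumsum(lens)[:-1]
    coding = new_mrna[cds_start - 1:]
    coding = coding[: len(coding) // 3 * 3]
    prot = str(Seq(coding).translate())
    if "*" not in prot:
        return "processed_transcript"
    stop_end = cds_start - 1 + (prot.index("*") + 1) * 3
    if len(junctions) and junctions[-1] - stop_end > ptc:
        return "NMD"
    return "coding"
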