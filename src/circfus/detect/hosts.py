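"""Host-gene annotation of called junctions."""

from __future__ import annotations

from ..models import CircJunction, Gene

_BIOTYPE_LABEL = {
    "protein_coding": "protein-coding",
}


def _label(biotype: str) -> str:
    return _BIOTYPE_LABEL.get(biotype, "non-coding")


def annotate_junctions(junctions: list[CircJunction], genes: list[Gene]) -> list[CircJunction]:
    """Assign host gene(s) and biotype; drop junctions whose boundaries fall
    into two genes that do not overlap each other (likely mapping errors)."""
    out = []
    for j in junctions:
        at_start = [g for g in genes if g.chrom == j.chrom and g.start <= j.start < g.end]
        at_end = [g for g in genes if g.chrom == j.chrom and g.start < j.end <= g.end]
        both = [g for g in at_start if g in at_end]
        if both:
            j.host_genes = [g.gene_id for g in both]
            j.host_biotype = _label(both[0].biotype)
        elif at_start and at_end:
            # boundaries in two different genes
            if any(a.overlaps(b) for a in at_start for b in at_end):
                j.host_genes = sorted({g.gene_id for g in at_start + at_end})
                j.host_biotype = _label((at_start + at_end)[0].biotype)
            else:
                continue  # spanning two non-overlapping genes
        elif at_start or at_end:
            g = (at_start or at_end)[0]
            j.host_genes = [g.gene_id]
            j.host_biotype = _label(g.biotype)
        else:
            j.host_genes = []
            j.host_biotype = "no gene"
        out.append(j)
    return out
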