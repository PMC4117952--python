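import pytest

import polyaflow as pf
from polyaflow import simulate as sim
from polyaflow.params import MTR_LIKE


@pytest.fixture(scope="session")
def params():
    return MTR_LIKE


@pytest.fixture(scope="session")
def bundle_sd0():
    """Synthetic bundle with zero cleavage jitter (exact recovery regime)."""
    cfg = pf.SimConfig(seed=11, microheterogeneity_sd=0)
    genome, transcripts, models, truth = sim.simulate_genome(cfg)
    tags = sim.simulate_tags(genome, models, truth, cfg)
    return dict(cfg=cfg, genome=genome, transcripts=transcripts,
                models=models, truth=truth, tags=tags)


@pytest.fixture(scope="session")
def bundle_jitter():
    """Synthetic bundle with realistic microheterogeneity (sd = 3 nt)."""
    cfg = pf.SimConfig(seed=7, microheterogeneity_sd=3.0)
    genome, transcripts, models, truth = sim.simulate_genome(cfg)
    tags = sim.simulate_tags(genome, models, truth, cfg)
    return dict(cfg=cfg, genome=genome, transcripts=transcripts,
                models=models, truth=truth, tags=tags)


def make_gene(gene_id, chrom, strand, start, *, utr5=80, exons=(150, 150),
              introns=(100,), utr3=150, chrom_length=50_000, params=MTR_LIKE,
              downstream_limit=None):
    """Hand-built single-transcript gene model (extension applied)."""
    blocks = [(utr5, "5UTR")]
    for i, e in enumerate(exons):
        blocks.append((e, "CDS"))
        if i < len(exons) - 1:
            blocks.append((introns[i], "intron"))
    if utr3:
        blocks.append((utr3, "3UTR"))
    if strand == "-":
        blocks = blocks[::-1]
    pos = start
    segs, ex, cds, u5, u3 = [], [], [], [], []
    cur = None
    for length, lab in blocks:
        iv = (pos, pos + length)
        segs.append((pos, pos + length, lab))
        if lab == "intron":
            if cur:
                ex.append(tuple(cur))
                cur = None
        else:
            if cur is None:
                cur = [iv[0], iv[1]]
            else:
                cur[1] = iv[1]
            {"CDS": cds, "5UTR": u5, "3UTR": u3}[lab].append(iv)
        pos += length
    if cur:
        ex.append(tuple(cur))
    t = pf.Transcript(transcript_id=f"{gene_id}.1", gene_id=gene_id, chrom=chrom,
                      strand=strand, exons=tuple(ex), cds=tuple(cds),
                      utr5=tuple(u5), utr3=tuple(u3))
    model = pf.merge_gene([t])
    pf.extend_model(model, chrom_length, params, downstream_limit=downstream_limit)
    return model


def tag(chrom, strand, pos, count=1, tag_id=None, mate="paired_unique"):
    return pf.MappedTag(tag_id=tag_id or f"t{chrom}_{strand}_{pos}", chrom=chrom,
                        strand=strand, cleavage_pos=pos, count=count,
                        mate_status=mate)


def pac(chrom, strand, summit, tag_count=1, pac_id=None):
    return pf.PAC(pac_id=pac_id or f"P{chrom}_{strand}_{summit}", chrom=chrom,
                  strand=strand, start=summit, end=summit + 1, summit=summit,
                  tag_count=tag_count, n_positions=1)
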