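"""End-to-end orchestration: translate, select, refine, call, quantify.

``process_sample`` takes per-source candidate records for one sample and
returns the refined alignment stream; ``run_cohort`` runs the whole
editing-discovery stack over a simulated (or externally loaded) cohort:
de novo calling per sample, cohort-level rescue of known database sites,
and per-sample read reports over the final site panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import calling, quantify
from .competitive import merge_selected, select_pairs
from .records import AlignmentRecord
from .refinement import SeedIndex, refine
from .transcript_db import translate_record


def process_sample(sources: dict[int, list[AlignmentRecord]], genome,
                   entries_by_name, *, index: SeedIndex | None = None,
                   window_kb: int = 100, min_qual: int = 20,
                   min_polyA: int = 6) -> list[AlignmentRecord]:
    """Competitive selection plus refinement for one sample.

    Candidates mapped to custom-database entries (their ``chrom`` is an
    entry name present in ``entries_by_name``) are translated to genomic
    coordinates first.
    """
    translated = []
    for recs in sources.values():
        for rec in recs:
            if rec.mapped and rec.chrom in entries_by_name:
                rec = translate_record(rec, entries_by_name)
            translated.append(rec)
    selected = merge_selected(select_pairs(translated))
    return refine(selected, genome, contigs=list(genome.keys()),
                  window_kb=window_kb, min_qual=min_qual,
                  min_polyA=min_polyA, index=index)


@dataclass
class CohortResult:
    refined_by_sample: dict[str, list[AlignmentRecord]]
    calls_by_sample: dict[str, list[calling.EditingSiteCall]]
    pass_sites: set[tuple]            # (chrom, pos, ref, alt) PASS de novo
    rescued: list[calling.EditingSiteCall] = field(default_factory=list)
    panel: list[quantify.Site] = field(default_factory=list)
    reports_by_sample: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def final_sites(self) -> set[tuple]:
        return self.pass_sites | {(c.chrom, c.pos, c.ref_allele, c.alt_allele)
                                  for c in self.rescued}


def run_cohort(ref, samples, *, min_alt_reads: int = 3, min_base_q: int = 20,
               min_map_q: int = 1, rescue_min_alt: int = 3,
               rescue_min_samples: int = 2) -> CohortResult:
    """Full discovery pipeline over a simulated cohort.

    ``ref`` is a :class:`editarm.simgen.SimReference`; ``samples`` a list
    of :class:`editarm.simgen.SampleReads`.  Germline subtraction uses the
    simulated germline VCF truth; the known-site table drives rescue.
    """
    from .simgen import write_candidate_alignments

    germline = {(r.chrom, r.pos, r.ref, r.alt)
                for r in ref.truth_snps.itertuples()}
    index = SeedIndex(ref.genome, list(ref.genome.keys()))

    refined_by_sample, calls_by_sample = {}, {}
    pass_sites: set[tuple] = set()
    for reads in samples:
        sources = write_candidate_alignments(ref, reads)
        refined = process_sample(sources, ref.genome, ref.entries_by_name,
                                 index=index)
        calls = calling.call_editing_sites(
            refined, ref.genome, ref.transcripts, germline=germline,
            somatic=set(), snp_table=None, paralog_db=ref.paralog_db,
            min_alt_reads=min_alt_reads, min_base_q=min_base_q,
            min_map_q=min_map_q)
        refined_by_sample[reads.sample_id] = refined
        calls_by_sample[reads.sample_id] = calls
        pass_sites |= {(c.chrom, c.pos, c.ref_allele, c.alt_allele)
                       for c in calls if c.is_pass}

    known_keys = [(r.chrom, r.pos, r.ref, r.alt)
                  for r in ref.known_sites.itertuples()]
    panel_keys = sorted(pass_sites | set(known_keys))
    panel = [quantify.Site(*k) for k in panel_keys]

    reports = {s: quantify.read_report(panel, recs, min_base_q, min_map_q)
               for s, recs in refined_by_sample.items()}
    rescued = calling.rescue_known_sites(ref.known_sites, reports,
                                         min_alt=rescue_min_alt,
                                         min_samples=rescue_min_samples)
    return CohortResult(refined_by_sample=refined_by_sample,
                        calls_by_sample=calls_by_sample,
                        pass_sites=pass_sites, rescued=rescued,
                        panel=panel, reports_by_sample=reports)
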