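"""Run the EST mapping QC chain on a handful of alignments.

Builds alignments that sit just above and below each quality threshold
(mapping length 100 bp, identity 96%, coverage-within-mapping 97%,
coverage-within-transcript 75%) plus an ambiguous double mapper, and
prints every verdict with the computed ratios.
"""

from lineagescan.psl import TranscriptAlignment
from lineagescan.transcript_map import filter_chain


def aln(tx, blocks, matches, mismatches, tx_len, t_start=1000):
    return TranscriptAlignment(
        transcript_id=tx, transcript_length=tx_len, chromosome="chr1",
        strand="+", t_start=t_start, t_end=t_start + blocks, matches=matches,
        mismatches=mismatches, block_sizes=[blocks], t_starts=[t_start],
        t_size=10**6, q_start=0, q_end=blocks,
    )


alignments = [
    aln("ok", 120, 116, 4, 150),            # identity 96.7%, all pass
    aln("too_short", 99, 99, 0, 130),       # mapping length below 100 bp
    aln("low_identity", 1000, 959, 41, 1250),
    aln("ambig", 1000, 1000, 0, 1250),          # best score 1000
    aln("ambig", 1000, 980, 20, 1250, 50_000),  # runner-up 960: 4% gap
]

verdicts, kept, status = filter_chain(alignments)
print("per-alignment QC:")
for v in verdicts:
    print(f"  {v.transcript_id:<13} {v.status:<5} "
          f"id={v.identity:5.1f}% cov_map={v.coverage_mapping:5.1f}% "
          f"cov_tx={v.coverage_transcript:5.1f}% "
          f"failed={','.join(v.failed_criteria) or '-'}")
print("\nper-transcript outcome (after best-mapping resolution):")
for tx, s in sorted(status.items()):
    print(f"  {tx:<13} {s}")
# 'ambig' is discarded because its two mappings score within 5% of each
# other; a transcript mapping equally well to two loci cannot be
# assigned to a gene unambiguously.
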