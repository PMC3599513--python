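"""Duplication-origin inference from a paralog table.

Rebuilds the published worked example: of 66 orphan genes, 24 have a
paralog and 5 of those paralogs are evolutionarily conserved, so 36.4%
have paralogs and 7.6% show evidence of origin by duplication followed
by rapid divergence.
"""

from lineagescan.duplication import ParalogRecord, infer_origin
from lineagescan.phylostrat import ConservationCall

calls = {f"o{i}": ConservationCall(f"o{i}", "ORPHAN") for i in range(66)}
calls.update({f"e{i}": ConservationCall(f"e{i}", "EC") for i in range(5)})
calls.update({f"x{i}": ConservationCall(f"x{i}", "CTSG") for i in range(19)})

records = (
    [ParalogRecord(f"o{i}", f"e{i}", 30.0) for i in range(5)]        # conserved
    + [ParalogRecord(f"o{i}", f"x{i - 5}", 75.0) for i in range(5, 24)]
)

s = infer_origin(records, calls, "ORPHAN")
print(f"orphan genes:                      {s.n_total}")
print(f"  with >=1 paralog:                {s.n_with_paralog} "
      f"({100 * s.fraction_with_paralog:.1f}%)")
print(f"  with a conserved (EC) paralog:   {s.n_with_conserved_paralog} "
      f"({100 * s.fraction_duplication_origin:.1f}%)")
# A conserved paralog marks the lineage-specific gene as a diverged
# duplicate of an old gene; the fraction is a lower bound on the
# contribution of duplication to lineage-specific gene birth.
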