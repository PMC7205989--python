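"""Classify alignment hits against domain envelopes.

Builds a two-protein reference annotation table by hand, classifies three
alignment hits with the default 20 AA overlap cutoff, and prints the
verdicts.  A hit is IN_DOMAIN when more than 20 AA of its subject interval
fall inside an envelope; OUT_OF_DOMAIN when more than 20 aligned AA are
covered by no envelope; UNCLASSIFIED otherwise.
"""

from metagenehunt import RAT, DomainEnvelope, SimilarityRecord, classify_hit

rat = RAT(lengths={"GH13": 450, "GH3": 600, "GH3C": 200})
rat.add(DomainEnvelope("prot1", "GH13", 100, 300))
rat.add(DomainEnvelope("prot2", "GH3", 10, 400))
rat.add(DomainEnvelope("prot2", "GH3C", 250, 400))


def hit(query, md5, s_start, s_end):
    return SimilarityRecord(query, md5, 92.0, s_end - s_start + 1, 2, 0,
                            1, 100, s_start, s_end, 1e-12, 88.0)


hits = [
    hit("read_a", "prot1", 280, 350),   # 21 AA inside GH13 -> transferred
    hit("read_b", "prot1", 305, 360),   # entirely in the C-terminal flank
    hit("read_c", "prot2", 200, 320),   # spans GH3 and its GH3C subdomain
]

print(f"{'query':8s} {'verdict':14s} {'domain':6s} {'in_aa':>5s} {'out_aa':>6s} ambiguous")
for h in hits:
    res = classify_hit(h, rat.envelopes_for(h.subject_md5), cutoff=20)
    print(f"{res.query_id:8s} {res.classification.value:14s} "
          f"{res.assigned_domain or '-':6s} {res.overlap_aa:5d} "
          f"{res.outside_aa:6d} {res.ambiguous}")

# read_c overlaps both GH3 (121 AA) and GH3C (71 AA): it is assigned to the
# larger overlap and flagged ambiguous so it counts toward one domain only.
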