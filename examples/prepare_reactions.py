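"""From reaction-SMILES lines to curated seq2seq task pairs.

Reading canonicalizes every component (atom maps stripped), curation drops
no-ops and duplicates, and pair construction encodes both sides in the
chosen notation — forward (reactants+reagents -> products) or retro.
"""

from fragsmiles import curate, make_pair, read_reactions, tag_stereo

lines = [
    "CCO.CC(=O)O>>CCOC(C)=O",                      # esterification
    "CC(=O)O.CCO>>CCOC(C)=O",                      # duplicate (reordered)
    "CCO>>CCO",                                    # no-op
    "C[C@@H](Br)CC.[N-]=[N+]=[N-]>>C[C@H](N=[N+]=[N-])CC",  # SN2 inversion
]
records, log = read_reactions(lines)
records, log = curate(records, log)
print(f"kept {len(records)} records; rejections: {dict(log.counts())}")

for rec in records:
    has, tag = tag_stereo(rec)
    print(f"  {rec.record_id}: stereo={tag}")
    fwd = make_pair(rec, "forward", "fragsmiles")
    print(f"    source: {fwd.source}")
    print(f"    target: {fwd.target}")

# The esterification survives with the duplicate and no-op dropped; the
# SN2 record is tagged 'stereoselective' because the center's parity flips
# along with the substitution.
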