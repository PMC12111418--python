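"""Codon usage and RSCU over the 13 protein-coding genes.

RSCU > 1 marks codons used more often than expected under uniform usage
within their synonymous family; fish mitogenomes prefer A-ending codons.
"""

import mitochar as mc

record = mc.simulate_mitogenome(seed=1)
code = mc.get_code()  # vertebrate mitochondrial (table 2)

cds_set = [record.feature_sequence(f) for f in record.pcgs]
table = mc.rscu(mc.count_codons(cds_set, code), code)

print(f"total encoded amino acids: {table.total}")
usage = mc.amino_acid_usage(table.counts, code)
top = max(usage, key=lambda aa: usage[aa][0])
low = min(usage, key=lambda aa: usage[aa][0])
print(f"most used residue: {top} ({usage[top][0]}, {usage[top][1]:.1f}%)")
print(f"least used residue: {low} ({usage[low][0]}, {usage[low][1]:.2f}%)")
print(f"preferred codons (RSCU > 1): {len(table.preferred)}")
best = max(table.preferred, key=lambda c: table.rscu[c])
print(f"highest RSCU: {best} = {table.rscu[best]:.2f}")
# 3794 amino acids is the template's codon capacity: every complete stop
# codon is excluded and incomplete stops contribute no codon.
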