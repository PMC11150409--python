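"""Convert amino-sugar biomarkers to necromass carbon and call qPCR genes.

Muramic acid is bacteria-specific and glucosamine mostly fungal, so the two
biomarkers split soil necromass C into bacterial and fungal pools.
"""

from necromap.chem import CtRecord, mnc_from_amino_sugars, qpcr_call, qpcr_relative_quant

est = mnc_from_amino_sugars(glun=1.0, mura=0.1)
print(f"GluN=1.0, MurA=0.1 mg/g -> fungal {est.fungal_C:.3f}, "
      f"bacterial {est.bacterial_C:.3f}, total {est.total_C:.3f} mg C/g")
print("-> a typical fungal-dominated topsoil: ~63% of necromass C is fungal.")

est = mnc_from_amino_sugars(glun=0.1, mura=0.2)
print(f"\nGluN=0.1, MurA=0.2 mg/g -> total {est.total_C:.1f} mg C/g, "
      f"clamped={est.clamped}")
print("-> bacteria-dominated sample: the fungal term went negative and was "
      "clamped to zero.")

print(f"\nCt=31 -> relative quantity {qpcr_relative_quant(31.0):.1f}")
print(f"Ct=27.67 -> relative quantity {qpcr_relative_quant(31 - 10/3):.1f}")
positive, q = qpcr_call(CtRecord("cbbL", "S0001", (31.0, 31.0, 31.0 - 10/3)))
print(f"three replicates (31, 31, 27.67): positive={positive}, mean quantity {q:.1f}")
positive, q = qpcr_call(CtRecord("cbbL", "S0002", (31.0, 31.0, None)))
print(f"one replicate missing: positive={positive} (a gene must amplify in "
      "all three technical replicates)")
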