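"""Scoring the 12-item Type D proxy.

Shows the person-mean imputation rule (up to two missing items per
subscale), cross-wave imputation from an earlier survey, and the joint
cut-off classification (both subscales >= 3 means Type D).
"""

from pedvar import ItemResponseWave, classify_type_d, score_individual, score_subscale

print("complete subscale (1,1,1,1,1,1):", score_subscale([1, 1, 1, 1, 1, 1]))
print("two missing, person-mean imputed (2,2,2,2,.,.):",
      score_subscale([2, 2, 2, 2, None, None]))
print("three missing -> subscale missing:",
      score_subscale([0, 1, None, None, None, 2]))

# two survey waves: the later wave is more complete and wins; its one
# missing NA item is filled from the earlier wave
earlier = ItemResponseWave("person", wave=1,
                           na_items=[2, 1, 1, None, None, None],
                           si_items=[1, 1, None, None, None, None],
                           age_at_survey=25, sex="female")
later = ItemResponseWave("person", wave=3,
                         na_items=[None, 1, 2, 1, 1, 1],
                         si_items=[1, 1, 1, 0, 1, 1],
                         age_at_survey=29, sex="female")
rec = score_individual([earlier, later])
print(f"\nchosen wave age {rec.age}: na={rec.na} si={rec.si} "
      f"naxsi={rec.naxsi} type_d={rec.type_d}")
print("(na item 1 was imputed from wave 1, so na = 2+1+2+1+1+1 = 8;")
print(" si = 5 is above the cut-off of 3, na = 8 too -> Type D yes)")

print("\ncut-off rule with one subscale missing:")
print("  na missing, si=2 ->", classify_type_d(None, 2), "(cannot reach cut-off)")
print("  na missing, si=7 ->", classify_type_d(None, 7), "(undecidable)")
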