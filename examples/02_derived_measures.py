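"""Closed-form clinical derivations for a single dog.

Shows the allometric (Wesselowski) indexing of mitral valve measures,
jet and prolapse grading, the age-weighted severity score, the
morphometric body indexes, and the stage-B1 eligibility flags.
"""

from mitralmorph import (
    DogRecord,
    MorphometricProfile,
    derive_measures,
    grade_mvp,
)

dog = DogRecord(
    dog_id="demo", age=4.16, sex="F", neutered=False, weight=9.15,
    coat="blenheim", bcs=5, murmur_grade=1, la_ao=1.42, lviddn=1.55,
    mvp_grade=grade_mvp("below_P"),            # leaflets under the P line
    arj_laa_pct=18.0, jet_all_systoles=True,   # mild jet, 18 % of LA area
    amvl=1.60, amvw=0.35, amva=0.45, mvad=1.77, mvas=1.48, si=1.37,
    morpho=MorphometricProfile(wh=29.2, bl=33.75, cw=12.25, th=14.95,
                               tw=11.95, tl=20.15, tc1=47.0, tc2=47.5,
                               tc3=45.5, hl=7.7, nl=3.2, hw=7.75, ha=115.0),
)
dog.validate()
d = derive_measures(dog)

print(f"indexed AMVL = {d.amvl_i:.4f} cm/kg^0.37   (raw 1.60 cm, 9.15 kg)")
print(f"indexed AMVA = {d.amva_i:.4f} cm^2/kg^0.78")
print(f"jet grade    = {d.jet_grade}  (18 % of LA area, all systoles -> mild)")
print(f"severity     = {d.severity:.3f}  ((MVP {dog.mvp_grade} + jet "
      f"{d.jet_grade}) * 5 / {dog.age} y)")
print(f"spherical LV = {d.spherical_flag}  (SI {dog.si} < 1.65)")
print(f"stage B1     = {d.b1_eligible}  (LA/Ao {dog.la_ao} < 1.6, "
      f"LVIDDN {dog.lviddn} < 1.7)")
idx = d.indexes
print(f"cephalic index {idx.cephalic_index:.2f}, thoracic index "
      f"{idx.thoracic_index:.2f}, craniofacial ratio "
      f"{idx.craniofacial_ratio:.2f}")
print("Higher cephalic index / lower craniofacial ratio = more "
      "brachycephalic head shape.")
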