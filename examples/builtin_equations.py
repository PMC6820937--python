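"""Estimate GFR for one patient with CKD-EPI, MDRD and the glycemia-aware equations.

Builds a single examination, runs the three estimators and prints the
results side by side.  The glycemia-aware prediction responds to fasting
glucose and HbA1c, which the creatinine-only equations ignore.
"""

from glygfr import Examination, ckd_epi, load_builtin, mdrd, predict_equation

# a 49-year-old woman with poorly controlled type 2 diabetes
exam = Examination(
    subject_id="example", exam_index=1,
    age=49, sex="F", height=1.61, weight=94.0,
    scr=0.50, fpg=214.0, hba1c=9.7,
)

pima = load_builtin("pima")

print(f"CKD-EPI eGFR        : {ckd_epi(exam.sex, exam.age, exam.scr):7.1f} mL/min/1.73m2")
print(f"MDRD eGFR           : {mdrd(exam.sex, exam.age, exam.scr):7.1f} mL/min/1.73m2")
print(f"glycemia-aware aGFR : {predict_equation(pima, exam):7.1f} mL/min/1.73m2")

# the same patient with near-normal glycemia
exam2 = Examination(
    subject_id="example", exam_index=2,
    age=49, sex="F", height=1.61, weight=94.0,
    scr=0.50, fpg=100.0, hba1c=5.8,
)
print(f"... with FPG 100 / HbA1c 5.8, glycemia-aware aGFR drops to "
      f"{predict_equation(pima, exam2):.1f} (CKD-EPI is unchanged: "
      f"{ckd_epi(exam2.sex, exam2.age, exam2.scr):.1f})")
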