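# Base-case inputs and uncertainty distributions for the eConsultant
# cost-minimisation model (AUD 2020/21, hospital provider perspective).
# Probabilities carry beta uncertainty from their source counts, times and
# attendance costs gamma (shape/rate), staff rates and the attendance-cost
# scale variable normal.
parameters:
- id: p_new_patient
  label: New patient (case mix)
  base: 0.962
  units: proportion
  role: probability
  family: beta
  params: {alpha: 125, beta: 5}
- id: p_dna
  label: DNA, face-to-face attendances
  base: 0.06
  units: proportion
  role: probability
  family: beta
  params: {alpha: 6, beta: 94}
- id: p_subsequent_f2f_new
  label: Subsequent face-to-face attendance, new
  base: 0.152
  units: proportion
  role: probability
  family: beta
  params: {alpha: 19, beta: 106}
- id: p_subsequent_f2f_review
  label: Subsequent face-to-face attendance, review
  base: 0.143
  units: proportion
  role: probability
  family: beta
  params: {alpha: 1, beta: 6}
- id: p_f2f_new
  label: Face-to-face attendance, new
  base: 0.779
  units: proportion
  role: probability
  family: beta
  params: {alpha: 106, beta: 30}
- id: p_f2f_review
  label: Face-to-face attendance, review
  base: 0.849
  units: proportion
  role: probability
  family: beta
  params: {alpha: 298, beta: 53}
- id: p_video_new
  label: Video attendance given not face-to-face, new
  base: 0.067
  units: proportion
  role: probability
  family: beta
  params: {alpha: 2, beta: 28}
- id: p_video_review
  label: Video attendance given not face-to-face, review
  base: 0.075
  units: proportion
  role: probability
  family: beta
  params: {alpha: 4, beta: 49}
- id: t_admin_new
  label: Administration time for eConsult, new
  base: 20.0
  units: min
  role: time
  family: gamma
  params: {alpha: 16.0, rate: 0.8}
- id: t_admin_review
  label: Administration time for eConsult, review
  base: 10.0
  units: min
  role: time
  family: gamma
  params: {alpha: 16.0, rate: 1.6}
- id: t_specialist_new_f2f
  label: Specialist eConsult time, new, subsequent F2F
  base: 16.32
  units: min
  role: time
  family: gamma
  params: {alpha: 1.60, rate: 0.09}
- id: t_specialist_review_f2f
  label: Specialist eConsult time, review, subsequent F2F
  base: 8.0
  units: min
  role: time
  family: gamma
  params: {alpha: 1.78, rate: 0.22}
- id: t_specialist_new_no_f2f
  label: Specialist eConsult time, new, no subsequent F2F
  base: 28.82
  units: min
  role: time
  family: gamma
  params: {alpha: 2.71, rate: 0.09}
- id: t_specialist_review_no_f2f
  label: Specialist eConsult time, review, no subsequent F2F
  base: 13.0
  units: min
  role: time
  family: gamma
  params: {alpha: 22.53, rate: 1.73}
- id: rate_admin
  label: Cost for administration officer staff
  base: 0.72
  units: AUD/min
  role: rate
  family: normal
  params: {mu: 0.72, sigma: 0.07}
- id: rate_specialist
  label: Cost for specialist staff
  base: 3.59
  units: AUD/min
  role: rate
  family: normal
  params: {mu: 3.59, sigma: 0.36}
- id: c_f2f_new
  label: Outpatient face-to-face cost, new
  base: 638.50
  units: AUD
  role: cost
  family: gamma
  params: {alpha: 3.835, rate: 0.006}
- id: c_f2f_review
  label: Outpatient face-to-face cost, review
  base: 319.69
  units: AUD
  role: cost
  family: gamma
  params: {alpha: 2.629, rate: 0.008}
- id: c_video_new
  label: Outpatient video cost, new
  base: 574.75
  units: AUD
  role: cost
  family: gamma
  params: {alpha: 1.061, rate: 0.002}
- id: c_video_review
  label: Outpatient video cost, review
  base: 276.07
  units: AUD
  role: cost
  family: gamma
  params: {alpha: 2.075, rate: 0.008}
- id: c_telephone_new
  label: Outpatient telephone cost, new
  base: 282.61
  units: AUD
  role: cost
  family: gamma
  params: {alpha: 2.439, rate: 0.008}
- id: c_telephone_review
  label: Outpatient telephone cost, review
  base: 239.47
  units: AUD
  role: cost
  family: gamma
  params: {alpha: 2.821, rate: 0.012}
- id: attendance_scale
  label: Scale on subsequent attendance cost relative to traditional pathway
  base: 1.0
  units: ratio
  role: scale
  family: normal
  params: {mu: 1.0, sigma: 0.25}
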