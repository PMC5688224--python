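# Passive elastic joint moment model: double exponentials per joint
# (coefficients transcribed from Riener & Edrich, J Biomech 29:1019-1023, 1996).
#
# Anatomical angles in DEGREES: ankle plantarflexion positive, knee flexion
# positive, hip flexion positive. Moments in N m, positive in the positive-
# angle direction, so each curve has a negative (restoring) slope around the
# upright range. Each joint moment is
#   exp(exp1.const + sum_i exp1[i] * angle_i)
# - exp(exp2.const + sum_i exp2[i] * angle_i) + offset  [+ knee hard stop]
# The knee carries an additional exponential term producing a steep flexion
# moment as the knee approaches full extension (hard stop against
# hyperextension). The mapping to the model's joint-torque convention lives
# in quietstance.muscle and is pinned by restoring-direction checks.
ankle:
  exp1: {const: 2.1016, ankle: -0.0843, knee: -0.0176, hip: 0.0}
  exp2: {const: -7.9763, ankle: 0.1949, knee: 0.0008, hip: 0.0}
  offset: -1.792
knee:
  exp1: {const: 1.8000, ankle: -0.0460, knee: -0.0352, hip: 0.0217}
  exp2: {const: -3.9710, ankle: -0.0004, knee: 0.0495, hip: -0.0128}
  offset: -4.820
  hardstop: {const: 2.2200, knee: -0.1500}
hip:
  exp1: {const: 1.4655, ankle: 0.0, knee: -0.0034, hip: -0.0750}
  exp2: {const: 1.3403, ankle: 0.0, knee: -0.0226, hip: 0.0305}
  offset: 8.072
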