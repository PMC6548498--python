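"""Null quantiles of the Rao spacing statistic U (radians).

Upper-tail critical values U_alpha for uniform samples of size n,
derived from 100,000 seeded Monte-Carlo replicates per sample size.
Rows follow RAO_NS, columns RAO_ALPHAS (descending alpha).
"""

import numpy as np

RAO_NS = np.array([4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 22, 24, 26, 28, 30, 35, 40, 45, 50, 60, 70, 80, 90, 100, 120, 140, 170, 200, 250, 300, 400, 500])

RAO_ALPHAS = np.array([0.999, 0.99, 0.95, 0.9, 0.75, 0.5, 0.25, 0.1, 0.05, 0.025, 0.01, 0.005, 0.001])

RAO_QUANTILES = np.array([
    [0.23023, 0.49975, 0.85061, 1.07014, 1.45784, 1.95033, 2.48298, 2.92939, 3.25005, 3.55811, 3.85316, 4.01807, 4.29285],
    [0.36846, 0.69294, 1.01768, 1.21564, 1.58406, 2.02961, 2.48821, 2.93837, 3.19525, 3.41523, 3.69400, 3.88854, 4.28152],
    [0.53831, 0.83541, 1.15289, 1.33852, 1.67421, 2.07406, 2.50718, 2.89868, 3.15845, 3.37562, 3.61061, 3.78080, 4.12382],
    [0.62853, 0.93403, 1.24406, 1.42156, 1.73586, 2.11314, 2.50623, 2.87774, 3.09923, 3.29516, 3.53440, 3.69984, 4.01371],
    [0.72132, 1.02146, 1.31212, 1.48006, 1.78159, 2.13730, 2.50651, 2.85231, 3.06797, 3.25645, 3.47204, 3.61554, 3.91467],
    [0.80333, 1.09847, 1.37706, 1.53852, 1.82673, 2.15929, 2.50646, 2.83255, 3.03138, 3.19792, 3.41585, 3.55864, 3.83166],
    [0.89725, 1.16238, 1.43309, 1.58616, 1.85688, 2.17368, 2.50515, 2.81560, 3.00069, 3.16309, 3.35811, 3.48828, 3.77085],
    [0.94636, 1.21065, 1.47534, 1.62546, 1.88669, 2.19103, 2.50731, 2.79702, 2.97563, 3.13616, 3.31967, 3.44082, 3.70308],
    [0.99211, 1.26446, 1.51904, 1.66266, 1.91189, 2.20277, 2.50377, 2.78304, 2.95360, 3.10466, 3.28323, 3.41129, 3.66401],
    [1.04203, 1.29704, 1.54914, 1.68653, 1.92654, 2.20546, 2.49592, 2.76543, 2.92864, 3.06941, 3.24624, 3.35877, 3.62824],
    [1.09439, 1.34312, 1.58144, 1.71569, 1.94704, 2.21563, 2.49444, 2.75217, 2.90959, 3.04799, 3.21251, 3.32679, 3.54072],
    [1.13006, 1.37135, 1.60576, 1.73580, 1.96049, 2.22220, 2.49167, 2.74078, 2.88842, 3.02210, 3.17300, 3.27725, 3.50947],
    [1.15769, 1.40042, 1.62665, 1.75561, 1.97569, 2.22614, 2.48767, 2.72905, 2.87686, 3.00695, 3.15560, 3.26063, 3.46642],
    [1.19367, 1.42853, 1.65409, 1.77740, 1.98773, 2.23070, 2.48359, 2.71802, 2.86280, 2.98883, 3.13078, 3.23175, 3.44378],
    [1.23426, 1.45457, 1.67262, 1.79323, 1.99863, 2.23954, 2.48335, 2.70782, 2.84548, 2.96469, 3.11383, 3.21654, 3.39703],
    [1.26045, 1.47691, 1.69273, 1.80849, 2.00889, 2.24147, 2.47935, 2.70138, 2.83306, 2.95019, 3.09108, 3.18190, 3.36568],
    [1.28351, 1.50186, 1.70448, 1.82095, 2.01789, 2.24325, 2.47970, 2.69178, 2.82210, 2.93888, 3.07800, 3.16996, 3.35771],
    [1.31834, 1.53474, 1.73563, 1.84714, 2.03341, 2.25168, 2.47292, 2.67937, 2.80352, 2.91351, 3.04520, 3.12487, 3.29310],
    [1.36970, 1.56994, 1.76252, 1.86920, 2.04865, 2.25668, 2.46828, 2.66353, 2.78112, 2.88452, 3.00478, 3.08418, 3.24635],
    [1.40238, 1.60371, 1.78677, 1.88882, 2.06070, 2.25924, 2.46337, 2.65330, 2.76669, 2.87064, 2.98764, 3.06364, 3.22328],
    [1.42667, 1.62875, 1.80794, 1.90753, 2.07400, 2.26449, 2.46095, 2.64149, 2.75133, 2.84713, 2.96074, 3.04446, 3.18499],
    [1.46702, 1.64724, 1.82579, 1.91962, 2.08140, 2.26878, 2.45824, 2.63117, 2.73746, 2.82976, 2.94213, 3.02017, 3.16969],
    [1.53317, 1.70495, 1.86243, 1.95129, 2.10112, 2.27481, 2.45056, 2.61082, 2.70927, 2.79619, 2.89725, 2.96765, 3.11173],
    [1.57613, 1.73629, 1.89198, 1.97415, 2.11708, 2.27980, 2.44578, 2.59673, 2.68890, 2.76793, 2.85873, 2.92011, 3.06118],
    [1.61493, 1.77426, 1.91900, 1.99750, 2.13087, 2.28285, 2.43784, 2.57861, 2.66462, 2.73756, 2.82588, 2.88075, 3.00428],
    [1.65339, 1.80109, 1.93866, 2.01306, 2.14037, 2.28544, 2.43287, 2.56817, 2.64769, 2.71750, 2.80167, 2.86416, 2.97365],
    [1.70831, 1.84360, 1.97235, 2.04065, 2.15787, 2.29001, 2.42370, 2.54485, 2.61837, 2.68346, 2.75837, 2.81117, 2.91678],
    [1.74372, 1.87946, 1.99721, 2.06238, 2.16943, 2.29187, 2.41678, 2.52959, 2.59718, 2.65702, 2.72550, 2.77120, 2.86597],
    [1.78944, 1.90873, 2.02046, 2.07963, 2.17983, 2.29470, 2.41003, 2.51565, 2.58000, 2.63611, 2.70191, 2.74292, 2.82585],
    [1.81744, 1.92930, 2.03566, 2.09287, 2.18796, 2.29591, 2.40542, 2.50507, 2.56442, 2.61570, 2.67697, 2.72110, 2.80653],
    [1.84315, 1.95261, 2.05260, 2.10700, 2.19669, 2.29915, 2.40253, 2.49618, 2.55375, 2.60207, 2.65966, 2.69862, 2.78095],
    [1.88904, 1.98262, 2.07395, 2.12321, 2.20735, 2.30069, 2.39442, 2.48134, 2.53270, 2.57819, 2.63124, 2.66813, 2.74463],
    [1.92091, 2.00742, 2.09252, 2.13843, 2.21582, 2.30278, 2.38992, 2.46914, 2.51658, 2.55801, 2.60721, 2.64163, 2.71644],
    [1.95200, 2.03648, 2.11428, 2.15543, 2.22504, 2.30342, 2.38300, 2.45532, 2.49921, 2.53590, 2.57841, 2.61030, 2.67501],
    [1.97768, 2.05922, 2.12901, 2.16774, 2.23277, 2.30521, 2.37814, 2.44368, 2.48326, 2.51742, 2.55780, 2.58483, 2.64133],
    [2.01801, 2.08616, 2.15094, 2.18399, 2.24147, 2.30644, 2.37202, 2.43087, 2.46620, 2.49677, 2.53312, 2.55849, 2.61510],
    [2.04293, 2.10655, 2.16379, 2.19544, 2.24816, 2.30726, 2.36706, 2.42089, 2.45402, 2.48224, 2.51523, 2.53672, 2.58443],
    [2.07594, 2.13508, 2.18472, 2.21128, 2.25705, 2.30806, 2.36010, 2.40653, 2.43479, 2.45884, 2.48665, 2.50540, 2.54479],
    [2.10185, 2.15201, 2.19794, 2.22212, 2.26317, 2.30845, 2.35475, 2.39641, 2.42184, 2.44409, 2.46910, 2.48679, 2.52535],
])
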