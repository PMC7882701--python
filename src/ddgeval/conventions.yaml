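# Default sign conventions and output caps for common stability predictors.
#
# sign: pos  -> positive ddG means destabilizing (|ddG| = ddG for destabilizing)
# sign: neg  -> negative ddG means destabilizing; harmonization negates values
# cap:       -> maximum |ddG| the tool reports, or null for uncapped output
#
# The source analyses do not publish per-tool conventions or cap values.
# The entries below follow each tool's own documentation where available and
# are otherwise conservative guesses; edit this file (or pass your own map)
# to match the predictor versions you actually ran.
foldx5: {sign: pos, cap: null}
inps3d: {sign: neg, cap: 5.0}
rosetta: {sign: pos, cap: null}
popmusic: {sign: pos, cap: 5.0}
imutant: {sign: neg, cap: null}
sdm: {sign: neg, cap: null}
sdm2: {sign: neg, cap: null}
mcsm: {sign: neg, cap: null}
duet: {sign: neg, cap: null}
cupsat: {sign: neg, cap: null}
maestro: {sign: pos, cap: null}
encom: {sign: neg, cap: null}
dynamut: {sign: neg, cap: null}
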