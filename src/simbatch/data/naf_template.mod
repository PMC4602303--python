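TITLE NaF-style fast sodium channel (synthetic template)
: mod-format rendering of an edited XML channel description.
: Placeholders in single braces are filled from the channel document;
: literal mod-syntax braces are doubled for the template engine.

NEURON {{
    SUFFIX naf
    USEION na READ ena WRITE ina
    RANGE gmax
}}

PARAMETER {{
    gmax = 0.12 (S/cm2)
    mAlphaA = {mAlphaA}
    mAlphak = {mAlphak}
    mBetaA = {mBetaA}
    mBetak = {mBetak}
    hAlphaA = {hAlphaA}
    hAlphak = {hAlphak}
    hBetaA = {hBetaA}
    hBetak = {hBetak}
}}

STATE {{ m h }}
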