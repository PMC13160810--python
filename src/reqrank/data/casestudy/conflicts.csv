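label,conflict_type,improving,worsening,indicators,principles
Emergency power supply,physical,Power reliability,Equipment energy consumption / energy storage pressure,A1;D2,3;17;31;40
Information sharing and privacy protection,physical,Information integrity,Information leak,A5;D5,19;31;32
Functional integration and spatial accessibility,technical,34,36,B3;A4,
Intelligent automation and user control,technical,43,37,B4;C1,
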