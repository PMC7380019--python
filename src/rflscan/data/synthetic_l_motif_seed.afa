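; synthetic L-motif seed alignment (fixture, not a published motif model)
>L_seed_1
VVKYRTLFAGLCKANARFNIMEMFDEMVLIGIEPTE
>L_seed_2
VSKYRTKFAGLCKANARFNIGEMFDEMYLIGIEPTE
>L_seed_3
VVLYRTLFFGLCKANWRFNIMEMFDQMVLIGIEPTE
>L_seed_4
VVKYRTLFAGLPKANMHFNIMEMFDEMVLIGQEPTE
>L_seed_5
QVKYRMLFAGLCKANCRFNIFEMFDEMVLIGIEPTE
>L_seed_6
VVKYRELFPGLCKANARFNIMEKFDEMVLMGIEPTE
>L_seed_7
VVKYRPLFAGLCKANARFNEMEGFDEMVLIGIEPTF
>L_seed_8
VVKYRTLFFGLCKCNARRNIMEMFDEMVLIGREPTE
>L_seed_9
VVKYRTLFAGLCKAPARFNYMEMFSEMVLIGIEPTG
>L_seed_10
AVKYRTLFAGLCKPNASFNIMEMFSEMVLIGIEPTE
>L_seed_11
VVKYRTLFAGLCKANWRFIIMEMFDEMILGGIEPTE
>L_seed_12
VVHYRTLFDGLCKFNARFNIMESFDEMVLIGIEPTE
>L_seed_13
VVKYRTLFAGLCKANARFEIMEMFDEMVLRIIECTE
>L_seed_14
VVKYRTLFAGLCKKNARFNIMETFDEMVLIWIEPKE
>L_seed_15
VVKYRGLFAGLCKRNARFNIMEMFDEMVLIGISITE
>L_seed_16
VVKYRTLEAGLTKANARFNIMEMCDEMVLIGHEPTE
>L_seed_17
VVKYRTLFAGLCRINATFNIMEMFDEMVLPGIEPTE
>L_seed_18
VVKYRTLFAGLHKANARFNIMEMFWEMCLITIEPTE
>L_seed_19
VVYYRTLFAGLVKANARFNIMEMFDEMVLIGIEPKC
>L_seed_20
VVKYRYLFAGLCKANARFNMMEMYDFMVLIGIEPTE
>L_seed_21
NVKYRTLWAGLCKANARFNILEMFDEMFLIGIEPTE
>L_seed_22
FVKYRTLFAGLCKATARFNIMEMFDEMCLIGIEITE
>L_seed_23
VVKPRTLFPGLCKANARFNIMEMFAEMRLIGIEPTE
>L_seed_24
VVKYRTNFAGLCKANARFPIMEMVDEMVLIGIEPTM
>L_seed_25
VGKTRTLFAGLCYANARFNIMEMFDEMKLIGIEPTE
>L_seed_26
VVKYPLLFAGRCKANARFNIMEMFDEMVFIGIEPTE
>L_seed_27
VVKPRTLFAGLCKANARDNIMEMFDEVVLIGIEPIE
>L_seed_28
VVKYRTLFAHWCWANARFNIMEMFDEMVLIGGEPTE
>L_seed_29
VVKYQTLFAELCKANARHNIMEMFDEMVQIGIEPTE
>L_seed_30
VVKYRTLFAGLCKANADFQIMEMFDEMVLGGIEPTM
>L_seed_31
VVKYRTLFADLNKANARFNIMEMFDEMVLIGIEPNR
>L_seed_32
VVKYRTLFAGLCKANFRFNIMIMFHEMVLIGIEHTE
>L_seed_33
RSKYRTLFAGLCKANARFNIMEMFDEMALIGIEPTM
>L_seed_34
VVKYRTQFAGLCKAMARDNIMEMFDEMVRIGIEPTE
>L_seed_35
RVDYRPLFAGLCKANARFNIMEMFDRMVLIGIEPTE
>L_seed_36
VVKYRTLFDGLCKANARFNIMEMFDETVLIGEMPTE
>L_seed_37
VHKYRMYFAGLCKANAVFNIMEMFDEMVLIGIEPTE
>L_seed_38
VVKYRTLYAGLCKANAYNNIMEMFDEMVLIGIEPTG
>L_seed_39
VVKYRTLFAGLCKANARFNIMEGIDEMVLTGIQPTE
>L_seed_40
VVMYRTLFEGLCEANARHNIMEMFDEMVLIGIEPTE
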