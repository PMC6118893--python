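>Tcas_Antp synthetic-standin-alignment
RKRGRQTITRLQTLELEKEFRFNRYLTRRRQIEIAHALCLTLRQIDIWFQNRRMKWSKEN
>Bflo_Hox7
RKRGRQTTTRYQTLELEKEFTFNRYLTERRRIEIAHALCLTERQIFIWFQNRRMKWKKEN
>Ctel_Antp
RKRGRQTDTRHQTLELEKEFKFNRYLTRRRTIEICHALCLKERQIKIWFQNQDMKWKKEN
>Hrob_Antp
RKRGCQTYTRLQTLELEKEFHFNRYLTRRQRIEIAHALCLHERQIKDWFQNRRMKWKKEN
>Pdum_Antp
RKRCRQTYTRCQTLELEKEFTFNRYLTNRRRIEIAHALCLTERQIKSWFKNRQMKWDKEN
>Avir_Antp
RKRGGQTYTRWQTLELEKEFHFNRYLTERRRIEIYHALCLTERQIKIWFYNRRMKWHKEN
>Lana_Antp
RKRGRQTHTRNQTLELEKEFHFNRYLTFRRRIEIQHALCLTFRQIKIWFQNARMKWPKEN
>Ttra_Antp
RKRMRQTMTRYQTLELEKEFHFNRYLTRRRRIEIAHALCLTARQIKIWFRNRRMKWAKEN
>Cgig_Antp
RKRGDQTITRYQTLELEKEFNFNRYLTYRRRIEISHALCLEFRQIGIWFQNMRMKWKKEN
>Lgig_Antp
RKRGKQTYTRYQTLELEKEFDFNRYLTRRRRIEIYHALCLWERQIRIWFQNRRMKWKKEN
>Esco_Antp
RKRGRQTDTRGQTLELEKEFHFNRYLTTRRRIEIAHALCLTERQIKIWFQNRGMKWKKEN
>Obim_Antp
RKRGFQTLTRNQTLELEKEFHFNRYLTWRRDIEINHALCLERCQIKIWFQNNRMKWKKEN
>Slam_Antp
RKTFRQTFTVAQTLENEKEFHFNRYLTIRRKIEAWHALCLTERQMKIWFQNRTMKEKKEN
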