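class,cue
Nature and wildlife appreciation,wildlife
Nature and wildlife appreciation,nature
Nature and wildlife appreciation,birds
Nature and wildlife appreciation,whales
Nature and wildlife appreciation,animals
Nature and wildlife appreciation,penguin
Nature and wildlife appreciation,puffin
Nature and wildlife appreciation,seal
Nature and wildlife appreciation,naturelovers
Nature and wildlife appreciation,wildlifephotography
Nature and wildlife appreciation,fauna
Nature and wildlife appreciation,birdwatching
Recreational (beach),beach
Recreational (beach),sand
Recreational (beach),sun
Recreational (beach),swim
Recreational (beach),surf
Recreational (beach),summer
Recreational (beach),waves
Recreational (beach),holiday
Recreational (beach),vacation
Recreational (beach),coast
Recreational (underwater),diving
Recreational (underwater),scuba
Recreational (underwater),snorkel
Recreational (underwater),underwater
Recreational (underwater),reef
Recreational (underwater),coral
Recreational (underwater),ocean
Recreational (underwater),sealife
Recreational (underwater),freediving
Recreational (hiking),hiking
Recreational (hiking),trekking
Recreational (hiking),trail
Recreational (hiking),walk
Recreational (hiking),outdoors
Recreational (hiking),camping
Recreational (hiking),kayak
Aesthetic and wellbeing,beautiful
Aesthetic and wellbeing,landscape
Aesthetic and wellbeing,sunset
Aesthetic and wellbeing,sky
Aesthetic and wellbeing,relax
Aesthetic and wellbeing,happy
Aesthetic and wellbeing,paradise
Aesthetic and wellbeing,art
Aesthetic and wellbeing,wellbeing
Aesthetic and wellbeing,peaceful
Aesthetic and wellbeing,view
Cultural heritage,heritage
Cultural heritage,culture
Cultural heritage,history
Cultural heritage,museum
Cultural heritage,moai
Cultural heritage,statue
Cultural heritage,tradition
Cultural heritage,indigenous
Cultural heritage,music
Cultural heritage,food
Cultural heritage,design
Other (travel),travel
Other (travel),travelphotography
Other (travel),wanderlust
Other (travel),trip
Other (travel),explore
Other (travel),adventure
Other (travel),tourism
Other (travel),photo
Other (travel),photography
Other (travel),instagood
Other (travel),island
Other (travel),luxury
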